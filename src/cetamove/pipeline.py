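"""End-to-end pipeline: prefilter -> state-space fit -> persistence ->
segmentation -> currents -> energetics (-> routes when a depth grid is given).

Each stage writes its output to the run directory and is logged as one JSON
line (stage, inputs, outputs, SHA-256 hashes); the manifest ties a run to its
configuration and seed so a rerun with identical inputs reproduces identical
hashes for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import energetics, segmentation
from .currents import attach_currents
from .io_formats import GriddedField, RunConfig, write_track
from .persistence import MovePersistenceModel
from .prefilter import FilterSettings, sda_filter
from .routes import DepthGrid, least_cost_path, mean_position, route_comparison
from .ssm import CrwModel


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], meta: dict | None = None):
        self.stages.append({
            "stage": stage,
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _sha256(v) for k, v in outputs.items()},
            "meta": meta or {},
        })

    def write(self, path: Path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


@dataclass
class PipelineResult:
    manifest: PipelineManifest
    track: pd.DataFrame
    phases: list
    calving: "segmentation.CalvingResult | None"
    budgets: dict
    routes: dict


def run_pipeline(
    obs,
    out_dir,
    config: RunConfig | None = None,
    current_field: GriddedField | None = None,
    depth_grid: DepthGrid | None = None,
    require_currents: bool = False,
    n_phases: int | None = None,
    log=print,
) -> PipelineResult:
    """Run every stage on a set of Argos observations.

    ``obs`` is a time-sorted list of ArgosObservation (e.g. from
    ``read_argos``).  ``n_phases`` fixes the segment count of the phase
    segmentation (analyst-chosen K); by default the threshold rule decides.
    Failures stop the pipeline and carry the stage name.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(config=dataclasses.asdict(config), seed=config.seed)

    def _log(stage, msg):
        log(json.dumps({"stage": stage, "t": time.strftime("%H:%M:%S"), "msg": msg}))

    # -- prefilter ----------------------------------------------------------
    try:
        settings = FilterSettings(vmax=config.vmax)
        kept, report = sda_filter(obs, settings)
        _log("prefilter", f"kept {len(kept)}/{len(obs)} fixes")
    except Exception as e:
        raise StageError("prefilter", e) from e

    # -- state-space fit and regular prediction -----------------------------
    try:
        model = CrwModel(kept, center=config.projection_center)
        # estimate an observation-error inflation alongside the process
        # parameters: reported CLS ellipses are trusted up to a global factor
        fit = model.fit(inflate_errors=True)
        track = fit.predict(config.interval_hours)
        _log("ssm", f"beta={fit.beta:.2e} tau={fit.tau:.2f} ll={fit.loglik:.1f}")
    except Exception as e:
        raise StageError("ssm", e) from e

    # -- movement persistence ------------------------------------------------
    try:
        mpm = MovePersistenceModel(track).fit()
        track["gamma"] = mpm.gamma
        _log("persistence", f"mean gamma {np.mean(mpm.gamma):.2f} "
             f"(sigma_g {mpm.sigma_g})")
    except Exception as e:
        raise StageError("persistence", e) from e

    # -- currents ------------------------------------------------------------
    if current_field is None and require_currents:
        raise StageError("currents", ValueError("current field required but missing"))
    try:
        if current_field is not None:
            track = attach_currents(track, current_field,
                                    resting_threshold=config.resting_threshold)
            _log("currents", "attached u/v and corrected speeds")
        else:
            track["speed_through_water"] = track["speed_over_ground"]
            track["behavior"] = np.where(
                track["speed_through_water"] <= config.resting_threshold,
                "resting", "transiting")
            _log("currents", "no field supplied; using speed over ground")
    except Exception as e:
        raise StageError("currents", e) from e

    # -- segmentation --------------------------------------------------------
    try:
        seg, phases = segmentation.detect_migration_phases(track, K=n_phases)
        labels = np.empty(len(track), dtype=object)
        for ph in phases:
            labels[ph.start:ph.end] = ph.label
        track["segment_label"] = labels
        seg_ids = np.zeros(len(track), dtype=int)
        for si, ph in enumerate(phases):
            seg_ids[ph.start:ph.end] = si
        track["segment_id"] = seg_ids
        _log("segmentation", f"{seg.K} segments on gamma")
        transit_ids = [i for i, ph in enumerate(phases) if ph.label == "transit"]
        calving = None
        if transit_ids:
            # calving produces a speed change during the final southbound
            # transit (the leg arriving at the breeding grounds), i.e. the
            # last transit phase before the final (northbound) one; with a
            # single transit phase, use it as a whole
            south = phases[transit_ids[-2]] if len(transit_ids) > 1 \
                else phases[transit_ids[0]]
            calving = segmentation.detect_calving(
                track.iloc[south.start:south.end].reset_index(drop=True))
            _log("calving", f"detected={calving.detected}")
    except Exception as e:
        raise StageError("segmentation", e) from e

    track_path = out_dir / "track.csv"
    write_track(track, track_path, "csv")
    manifest.record("track", {"track": track_path},
                    {"n_steps": len(track), "K": seg.K})

    # -- energetics ----------------------------------------------------------
    try:
        params = energetics.BioenergeticParams(**config.bioenergetics)
        budgets = {"deployment": energetics.budget(track, params,
                                                   resting_threshold=config.resting_threshold)}
        transit_phases = [ph for ph in phases if ph.label == "transit"]
        if transit_phases:
            mig_lo = transit_phases[0].start
            mig_hi = transit_phases[-1].end
            ts = pd.to_datetime(track["timestamp"])
            budgets["migration"] = energetics.budget(
                track, params,
                window=(ts.iloc[mig_lo], ts.iloc[mig_hi - 1] + pd.Timedelta(hours=6)),
                resting_threshold=config.resting_threshold)
        _log("energetics", {k: round(b.e_total_mj) for k, b in budgets.items()})
        budget_path = out_dir / "budget.json"
        budget_path.write_text(json.dumps(
            {k: b.to_dict() for k, b in budgets.items()}, indent=2))
        manifest.record("energetics", {"budget": budget_path})
    except Exception as e:
        raise StageError("energetics", e) from e

    # -- routes (optional) ---------------------------------------------------
    routes_out = {}
    if depth_grid is not None:
        try:
            res_ids = [i for i, ph in enumerate(phases) if ph.label == "residence"]
            if len(res_ids) >= 2:
                feed = phases[res_ids[0]]
                breed = phases[res_ids[-1]] if len(res_ids) == 2 else \
                    phases[res_ids[len(res_ids) // 2]]
                p_feed = mean_position(track["lon"].iloc[feed.start:feed.end],
                                       track["lat"].iloc[feed.start:feed.end])
                p_breed = mean_position(track["lon"].iloc[breed.start:breed.end],
                                        track["lat"].iloc[breed.start:breed.end])
                direct = least_cost_path(p_feed, p_breed, depth_grid)
                routes_out = {"direct": direct,
                              "comparison": route_comparison(
                                  track["lon"].to_numpy(), track["lat"].to_numpy(),
                                  direct, direct)}
                _log("routes", f"direct {direct.length_km:.0f} km")
        except Exception as e:
            raise StageError("routes", e) from e

    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    return PipelineResult(manifest=manifest, track=track, phases=phases,
                          calving=calving, budgets=budgets, routes=routes_out)
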