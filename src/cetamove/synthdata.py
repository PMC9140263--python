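"""Synthetic whale deployments with known ground truth.

Every stage of the pipeline is testable offline against scenarios generated
here: a phase plan (residence / transit segments with target persistence and
speed, and an optional mid-migration calving event that drops speed) drives
an AR(1) velocity process on a 6-hour grid; irregular Argos-like fixes with
class-dependent error ellipses, occasional gross outliers and invalid class-Z
rows are sampled from the true path; a smooth divergence-free toy current
field and a polygon-based depth grid complete the inputs.

The default scenario (:func:`paper_like_scenario`) mirrors the scales of a
real single-whale deployment in the Northeast Atlantic: 321 days, seven
movement phases, ~18,500 km of migration at median transit speeds near
1.9/1.7/1.3/1.5 m/s, and a calving event partway through the second
southbound transit.

One seed governs the whole scenario; independent sub-streams per component
keep, e.g., the observation noise stable when the current field changes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geodesy import AzimuthalEquidistant
from .io_formats import ArgosObservation, GriddedField
from .routes import DepthGrid
from .ssm import CLASS_DEFAULT_SD, ellipse_to_covariance

MAX_PLAUSIBLE_SPEED = 9.0  # m/s; faster sustained swimming is not simulable

#: Typical error-ellipse semi-major scale (m) by class for Kalman-processed
#: CLS exports.  Deliberately tighter than the conservative isotropic
#: fallback SDs used by the state-space model for fixes *without* ellipses
#: (those reflect worst-case least-squares class radii).
ELLIPSE_SCALE_M = {"3": 250.0, "2": 500.0, "1": 1000.0, "0": 2000.0,
                   "A": 2500.0, "B": 4500.0}


@dataclass
class Phase:
    name: str
    duration_days: float
    gamma: float                  # target movement persistence in [0, 1]
    speed: float                  # target mean speed, m/s
    heading: float | None = None  # degrees from north; None = no drift (residence)

    @property
    def is_transit(self) -> bool:
        return self.heading is not None


@dataclass
class CalvingEvent:
    """A mid-transit calving: a brief near-stationary dip, then slower travel.

    Observed calving events show a sharp decline to very slow speeds for
    about a day, after which travel resumes at a reduced pace.
    """

    day_offset: float             # days from deployment start
    speed_multiplier: float       # applied to target speed afterwards
    dip_days: float = 1.0         # duration of the very-slow period
    dip_speed: float = 0.3        # m/s during the dip


@dataclass
class ArgosSamplingSpec:
    fixes_per_day: float = 14.0
    class_mix: dict = field(default_factory=lambda: {
        "3": 0.10, "2": 0.15, "1": 0.20, "0": 0.20, "A": 0.20, "B": 0.15})
    outlier_rate: float = 0.02    # gross position errors (tens of km)
    z_rate: float = 0.01          # invalid class-Z rows

    def __post_init__(self):
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")


@dataclass
class CurrentFieldSpec:
    amplitude: float = 0.15       # m/s
    wavelength_deg: float = 10.0
    resolution_deg: float = 0.5
    time_step_hours: float = 24.0


@dataclass
class DepthGridSpec:
    resolution_deg: float = 1.0
    base_depth_m: float = 3000.0
    land_polygons: list = field(default_factory=list)   # shapely Polygons (lon/lat)


@dataclass
class ScenarioSpec:
    phases: list[Phase]
    start_lonlat: tuple[float, float] = (21.5, 70.0)
    start_time: _dt.datetime = _dt.datetime(2019, 1, 8, tzinfo=_dt.timezone.utc)
    projection_center: tuple[float, float] = (-20.0, 45.0)
    calving: CalvingEvent | None = None
    argos: ArgosSamplingSpec = field(default_factory=ArgosSamplingSpec)
    currents: CurrentFieldSpec = field(default_factory=CurrentFieldSpec)
    depth: DepthGridSpec = field(default_factory=DepthGridSpec)
    speed_cv: float = 0.3         # velocity fluctuation scale for transit phases
    #: memory of transit velocity fluctuations (AR coefficient per step);
    #: None couples it to the phase persistence
    transit_noise_gamma: float | None = None
    interval_hours: float = 6.0
    seed: int = 42

    def __post_init__(self):
        for p in self.phases:
            if p.duration_days <= 0:
                raise ValueError(f"phase {p.name!r}: duration must be positive")
            if not 0 <= p.gamma <= 1:
                raise ValueError(f"phase {p.name!r}: gamma must lie in [0, 1]")
            if p.speed < 0:
                raise ValueError(f"phase {p.name!r}: speed must be >= 0")
            if p.speed > MAX_PLAUSIBLE_SPEED:
                raise ValueError(
                    f"phase {p.name!r}: target speed {p.speed} m/s exceeds "
                    f"{MAX_PLAUSIBLE_SPEED} m/s"
                )

    @property
    def total_days(self) -> float:
        return sum(p.duration_days for p in self.phases)

    def _streams(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return (np.random.default_rng(kids[0]), np.random.default_rng(kids[1]),
                np.random.default_rng(kids[2]))


def paper_like_scenario(seed: int = 42, total_days: float = 321.0) -> ScenarioSpec:
    """Seven-phase scenario mirroring a full NEA round-trip migration.

    Residence in Norway, a fast transit to Iceland, an Iceland stopover, the
    long southbound transit with a calving-related speed drop, a breeding
    stopover, the northbound transit, and a final feeding residence.
    """
    final = total_days - 200.0
    if final <= 0:
        raise ValueError("total_days too short for the seven-phase plan")
    # residence persistence near zero mirrors the deep-ARS behaviour of
    # feeding/breeding residency; transits are strongly directed
    phases = [
        Phase("norway", 30, 0.10, 0.70),
        Phase("migration_south_1", 7, 0.90, 1.90, heading=248.0),
        Phase("iceland", 15, 0.10, 0.60),
        Phase("migration_south_2", 61, 0.90, 1.70, heading=222.0),
        Phase("west_indies", 16, 0.10, 0.50),
        Phase("migration_north", 71, 0.90, 1.50, heading=32.0),
        Phase("barents", final, 0.10, 0.80),
    ]
    # calving 24 days into the second southbound transit (day 30+7+15+24=76):
    # speed drops from 1.7 to 1.3 m/s
    return ScenarioSpec(phases=phases, calving=CalvingEvent(76.0, 1.3 / 1.7),
                        seed=seed)


def simulate_truth(spec: ScenarioSpec, current_field: GriddedField | None = None
                   ) -> pd.DataFrame:
    """True 6-hourly track with per-step labels.

    The swim velocity follows a per-phase AR(1): v_t = g v_{t-1} + (1-g) mu +
    eta, with drift mu set by the phase heading and target speed (zero for
    residence phases, where the fluctuation scale is chosen so the mean speed
    matches the target).  If ``current_field`` is given the position is
    advected by the ambient current on top of the swim velocity, so ground
    displacement = (swim + current) * dt while ``speed_true`` remains the
    speed through water.  Deterministic under the scenario seed.
    """
    rng, _, _ = spec._streams()
    dt_s = spec.interval_hours * 3600.0
    proj = AzimuthalEquidistant(*spec.projection_center)
    x0, y0 = proj.forward(*spec.start_lonlat)

    # the calving speed drop applies within the phase where the event falls
    calving_phase = None
    if spec.calving is not None:
        acc = 0.0
        for idx, p in enumerate(spec.phases):
            if acc <= spec.calving.day_offset < acc + p.duration_days:
                calving_phase = idx
                break
            acc += p.duration_days

    def _phase_moments(phase, speed):
        """Drift vector and stationary fluctuation SD for a phase.

        The mean velocity of each behavioural unit is pinned to the drift
        after simulation, so the drift magnitude is simply the target speed.
        """
        if phase.is_transit:
            s_st = spec.speed_cv * speed              # stationary per-axis SD
            h = np.radians(phase.heading)
            mu = speed * np.array([np.sin(h), np.cos(h)])
        else:
            mu = np.zeros(2)
            # stationary per-axis SD such that E|v| = speed for a 2D Gaussian
            s_st = speed / np.sqrt(np.pi / 2.0)
        return mu, s_st

    # behavioural units: phases, with the calving phase split at the event so
    # pre- and post-calving speeds are realised independently
    steps_per_day = 24.0 / spec.interval_hours
    units = []   # (phase, speed, n_steps, calved)
    day = 0.0
    for pidx, phase in enumerate(spec.phases):
        n_steps = int(round(phase.duration_days * steps_per_day))
        calved_from_start = (spec.calving is not None
                             and day >= spec.calving.day_offset)
        if pidx == calving_phase and not calved_from_start:
            n_pre = int(round((spec.calving.day_offset - day) * steps_per_day))
            n_pre = min(max(n_pre, 0), n_steps)
            n_dip = min(int(round(spec.calving.dip_days * steps_per_day)),
                        n_steps - n_pre)
            if n_pre:
                units.append((phase, phase.speed, n_pre, False))
            if n_dip:
                units.append((phase, spec.calving.dip_speed, n_dip, True))
            if n_steps - n_pre - n_dip:
                units.append((phase, phase.speed * spec.calving.speed_multiplier,
                              n_steps - n_pre - n_dip, True))
        else:
            units.append((phase, phase.speed, n_steps, calved_from_start))
        day += phase.duration_days

    # per-unit AR(1) velocities with centred innovations and the mean velocity
    # pinned to the target drift (a constant shift, i.e. the same AR model
    # with an adjusted drift, so per-step persistence is untouched)
    all_v = []
    for phase, speed, n_steps, _ in units:
        # transit: drift carries the heading persistence, fluctuations are
        # short-memory; residence: zero drift, fluctuation memory IS gamma
        g = phase.gamma
        if phase.is_transit and spec.transit_noise_gamma is not None:
            g = spec.transit_noise_gamma
        mu, s_st = _phase_moments(phase, speed)
        sd = s_st * np.sqrt(max(1.0 - g**2, 1e-6))
        eps = rng.standard_normal((n_steps, 2))
        eps -= eps.mean(axis=0)
        v = np.empty((n_steps, 2))
        w = rng.normal(0.0, s_st, 2)
        for k in range(n_steps):
            w = g * w + sd * eps[k]
            v[k] = mu + w
        v += mu - v.mean(axis=0)
        # rescale so the realised mean speed equals the target exactly (a
        # constant scale preserves the AR structure and persistence)
        ms = float(np.mean(np.hypot(v[:, 0], v[:, 1])))
        if ms > 0 and speed > 0:
            v *= speed / ms
        all_v.append(v)

    rows = []
    pos = np.array([x0, y0], dtype=float)
    t = pd.Timestamp(spec.start_time)
    step_td = pd.Timedelta(hours=spec.interval_hours)
    for (phase, speed, n_steps, calved), v in zip(units, all_v):
        for k in range(n_steps):
            drift = np.zeros(2)
            if current_field is not None:
                from .currents import sample_current

                lon0, lat0 = proj.inverse(pos[0], pos[1])
                cur = sample_current(current_field, lon0, lat0, t)
                drift = np.array([cur.u, cur.v])
            pos = pos + (v[k] + drift) * dt_s
            lon, lat = proj.inverse(pos[0], pos[1])
            rows.append({
                "timestamp": t, "lon": lon, "lat": lat,
                "x": pos[0], "y": pos[1],
                "speed_true": float(np.hypot(*v[k])),
                "gamma_true": phase.gamma,
                "phase": phase.name,
                "is_transit": phase.is_transit,
                "calved": bool(calved),
            })
            t = t + step_td
    return pd.DataFrame(rows)


def observe_argos(truth: pd.DataFrame, spec: ScenarioSpec) -> list[ArgosObservation]:
    """Irregular Argos-like fixes sampled from the true path.

    Fix times follow a Poisson process at the configured rate; positions are
    linearly interpolated from the true 6-hour path and perturbed with an
    anisotropic Gaussian error drawn from a class-dependent ellipse.  Gross
    outliers and class-Z rows are injected at the configured rates.
    """
    _, rng, _ = spec._streams()
    proj = AzimuthalEquidistant(*spec.projection_center)
    ts = pd.to_datetime(truth["timestamp"])
    t0, t1 = ts.iloc[0], ts.iloc[-1]
    span_days = (t1 - t0).total_seconds() / 86400.0
    n_fix = rng.poisson(spec.argos.fixes_per_day * span_days)
    fix_times = np.sort(np.floor(rng.uniform(0.0, (t1 - t0).total_seconds(), n_fix)))
    fix_times = np.unique(fix_times)
    n_fix = len(fix_times)

    tsec = (ts - t0).dt.total_seconds().to_numpy()
    x = np.interp(fix_times, tsec, truth["x"].to_numpy())
    y = np.interp(fix_times, tsec, truth["y"].to_numpy())

    classes = list(spec.argos.class_mix)
    probs = np.array([spec.argos.class_mix[c] for c in classes])
    out = []
    for i in range(n_fix):
        qc = classes[rng.choice(len(classes), p=probs)]
        scale = ELLIPSE_SCALE_M[qc]
        smaj = scale * rng.uniform(0.7, 1.3)
        smin = smaj * rng.uniform(0.4, 0.9)
        orient = rng.uniform(0.0, 180.0)
        cov = ellipse_to_covariance(smaj, smin, orient)
        err = np.linalg.cholesky(cov) @ rng.standard_normal(2)
        xi, yi = x[i] + err[0], y[i] + err[1]
        if rng.random() < spec.argos.outlier_rate:
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(6e4, 2.5e5)  # 60-250 km gross error
            xi += r * np.cos(ang)
            yi += r * np.sin(ang)
        if rng.random() < spec.argos.z_rate:
            qc = "Z"
        lon, lat = proj.inverse(xi, yi)
        out.append(ArgosObservation(
            timestamp=(t0 + pd.Timedelta(seconds=float(fix_times[i]))).to_pydatetime(),
            lon=lon, lat=lat, quality_class=qc,
            ellipse_semi_major=smaj, ellipse_semi_minor=smin,
            ellipse_orientation=orient,
        ))
    return out


def make_current_field(spec: ScenarioSpec, bbox=None) -> GriddedField:
    """Smooth divergence-free toy current field over the scenario's extent.

    Velocities derive from a doubly periodic streamfunction by central
    differences on a uniform nominal metric, so the same central-difference
    divergence vanishes identically (to rounding).  A slow temporal modulation
    preserves the property at every time slice.
    """
    _, _, rng = spec._streams()
    cs = spec.currents
    if bbox is None:
        bbox = (-80.0, 30.0, 8.0, 80.0)  # lon_min, lon_max, lat_min, lat_max
    lon_min, lon_max, lat_min, lat_max = bbox
    lons = np.arange(lon_min, lon_max + cs.resolution_deg / 2, cs.resolution_deg)
    lats = np.arange(lat_min, lat_max + cs.resolution_deg / 2, cs.resolution_deg)
    n_days = spec.total_days
    times = pd.date_range(spec.start_time.replace(tzinfo=None),
                          periods=int(n_days * 24 / cs.time_step_hours) + 2,
                          freq=pd.Timedelta(hours=cs.time_step_hours))

    dy0 = 110574.0 * cs.resolution_deg
    dx0 = 111320.0 * np.cos(np.radians((lat_min + lat_max) / 2)) * cs.resolution_deg
    LON, LAT = np.meshgrid(lons, lats)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
    wl = cs.wavelength_deg
    # streamfunction amplitude chosen so |grad psi| ~ amplitude
    A = cs.amplitude * min(dx0, dy0) * wl / cs.resolution_deg / (2 * np.pi)
    psi0 = A * np.sin(2 * np.pi * LON / wl + phase1) * np.sin(2 * np.pi * LAT / wl + phase2)

    nt = len(times)
    u = np.zeros((nt, len(lats), len(lons)))
    v = np.zeros((nt, len(lats), len(lons)))
    tmod = 0.5 + 0.5 * np.cos(2 * np.pi * np.arange(nt) / max(nt - 1, 1))
    for k in range(nt):
        psi = psi0 * (0.5 + 0.5 * tmod[k])
        uk = np.zeros_like(psi)
        vk = np.zeros_like(psi)
        uk[1:-1, :] = -(psi[2:, :] - psi[:-2, :]) / (2 * dy0)
        vk[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2 * dx0)
        u[k] = uk
        v[k] = vk
    return GriddedField(times=times.to_numpy(dtype="datetime64[ns]"),
                        lats=lats, lons=lons, u=u, v=v)


def make_depth_grid(spec: ScenarioSpec, bbox=None) -> DepthGrid:
    """Toy bathymetry: constant deep ocean with polygon land masses."""
    ds = spec.depth
    if bbox is None:
        bbox = (-80.0, 30.0, 8.0, 80.0)
    lon_min, lon_max, lat_min, lat_max = bbox
    lons = np.arange(lon_min, lon_max + ds.resolution_deg / 2, ds.resolution_deg)
    lats = np.arange(lat_min, lat_max + ds.resolution_deg / 2, ds.resolution_deg)
    depth = np.full((len(lats), len(lons)), ds.base_depth_m)
    for poly in ds.land_polygons:
        p = Polygon(poly) if not isinstance(poly, Polygon) else poly
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if p.contains(Point(lo, la)):
                    depth[i, j] = 0.0
    return DepthGrid(lats=lats, lons=lons, depth=depth)
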