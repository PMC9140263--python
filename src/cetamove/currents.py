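"""Ocean-current extraction and speed-through-water correction.

Whale displacement between fixes mixes active swimming with passive drift, so
speed over ground is corrected by subtracting the ambient surface current
vector: swim vector = ground vector - current vector.  Currents are sampled
nearest-in-time then nearest-in-space from a gridded u/v field (surface 0-5 m
currents standing in for swim-depth currents); masked coastal cells fall back
to the nearest valid neighbour within a configurable radius.

Sign convention for the decomposition: ``support`` is the current component
along the ground-track direction (positive = current pushes the whale along
its track); ``cross`` is the component 90 degrees counterclockwise from the
track direction (positive = current pushes to the left of travel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GriddedField


@dataclass
class CurrentAtStep:
    u: float
    v: float
    time_index: int
    lat_index: int
    lon_index: int
    time_offset_s: float
    fallback_distance_cells: int    # 0 when the nearest cell itself was valid
    missing: bool = False           # no valid cell within radius -> (0, 0)


def sample_current(field: GriddedField, lon, lat, when, max_radius_cells: int = 3
                   ) -> CurrentAtStep:
    """Nearest-in-time-then-space current at a position/time.

    Ties in time go to the earlier record; ties in space to the lower index.
    If the nearest cell is masked the search expands in square rings up to
    ``max_radius_cells``; beyond that the step is flagged missing and treated
    as zero current.
    """
    when64 = np.datetime64(pd.Timestamp(when).tz_localize(None)
                           if pd.Timestamp(when).tzinfo else pd.Timestamp(when), "ns")
    dt = np.abs((field.times - when64) / np.timedelta64(1, "s")).astype(float)
    ti = int(np.argmin(dt))  # argmin takes the first (earlier) on ties
    la = int(np.argmin(np.abs(field.lats - lat)))
    lo = int(np.argmin(np.abs(field.lons - lon)))

    mask = ~(np.isfinite(field.u[ti]) & np.isfinite(field.v[ti]))
    if not mask[la, lo]:
        return CurrentAtStep(float(field.u[ti, la, lo]), float(field.v[ti, la, lo]),
                             ti, la, lo, float(dt[ti]), 0)
    for r in range(1, max_radius_cells + 1):
        best = None
        for dla in range(-r, r + 1):
            for dlo in range(-r, r + 1):
                if max(abs(dla), abs(dlo)) != r:
                    continue
                a, b = la + dla, lo + dlo
                if 0 <= a < len(field.lats) and 0 <= b < len(field.lons) and not mask[a, b]:
                    key = (abs(dla) + abs(dlo), a, b)
                    if best is None or key < best[0]:
                        best = (key, a, b)
        if best is not None:
            _, a, b = best
            return CurrentAtStep(float(field.u[ti, a, b]), float(field.v[ti, a, b]),
                                 ti, a, b, float(dt[ti]), r)
    return CurrentAtStep(0.0, 0.0, ti, la, lo, float(dt[ti]), max_radius_cells,
                         missing=True)


@dataclass
class SpeedCorrection:
    speed_through_water: float   # |ground vector - current vector|, m/s
    support: float               # current along track direction, m/s
    cross: float                 # current 90 deg CCW of track direction, m/s
    degenerate: bool = False     # zero ground displacement with nonzero current


def correct_speed(ground_vector, current_uv, dt_s: float) -> SpeedCorrection:
    """Speed through water from a ground displacement vector and a current.

    ``ground_vector`` is the displacement over the step in metres (east,
    north); ``current_uv`` the (u, v) current in m/s; ``dt_s`` the step
    duration.  The swim vector is ground velocity minus current.
    """
    if dt_s <= 0:
        raise ValueError("step duration must be positive")
    g = np.asarray(ground_vector, dtype=float) / dt_s
    c = np.asarray(current_uv, dtype=float)
    swim = g - c
    V = float(np.hypot(*swim))
    gnorm = float(np.hypot(*g))
    if gnorm == 0.0:
        return SpeedCorrection(float(np.hypot(*c)), 0.0, 0.0,
                               degenerate=bool(np.any(c != 0)))
    unit = g / gnorm
    support = float(c @ unit)
    perp = np.array([-unit[1], unit[0]])   # 90 deg counterclockwise
    cross = float(c @ perp)
    return SpeedCorrection(V, support, cross)


def classify_behavior(V: float, threshold: float = 0.5) -> str:
    """Resting (V <= threshold, inclusive) vs transiting (V > threshold)."""
    if V < 0:
        raise ValueError("speed through water cannot be negative")
    return "resting" if V <= threshold else "transiting"


def attach_currents(track: pd.DataFrame, field: GriddedField,
                    interval_s: float | None = None,
                    resting_threshold: float = 0.5,
                    max_radius_cells: int = 3) -> pd.DataFrame:
    """Append current columns and corrected speeds to a predicted track.

    For each step the current is sampled at the step's start position/time and
    assumed constant over the step.  Adds columns u/v/support/cross/
    speed_through_water/behavior/current_missing; returns a new frame.
    """
    track = track.reset_index(drop=True).copy()
    ts = pd.to_datetime(track["timestamp"])
    if interval_s is None:
        if len(ts) < 2:
            raise ValueError("cannot infer step interval from one step")
        interval_s = float((ts.iloc[1] - ts.iloc[0]).total_seconds())
    n = len(track)
    cols = {k: np.zeros(n) for k in
            ("u", "v", "support", "cross", "speed_through_water")}
    missing = np.zeros(n, dtype=bool)
    behavior = []
    xy = track[["x", "y"]].to_numpy(dtype=float) if {"x", "y"} <= set(track.columns) \
        else None
    for i in range(n):
        cur = sample_current(field, track["lon"].iloc[i], track["lat"].iloc[i],
                             ts.iloc[i], max_radius_cells=max_radius_cells)
        if i < n - 1:
            if xy is not None:
                gvec = xy[i + 1] - xy[i]
            else:  # fall back to local equirectangular displacement
                dlat = track["lat"].iloc[i + 1] - track["lat"].iloc[i]
                dlon = track["lon"].iloc[i + 1] - track["lon"].iloc[i]
                gvec = np.array([
                    dlon * 111320.0 * np.cos(np.radians(track["lat"].iloc[i])),
                    dlat * 110574.0,
                ])
        corr = correct_speed(gvec, (cur.u, cur.v), interval_s)
        cols["u"][i] = cur.u
        cols["v"][i] = cur.v
        cols["support"][i] = corr.support
        cols["cross"][i] = corr.cross
        cols["speed_through_water"][i] = corr.speed_through_water
        missing[i] = cur.missing
        behavior.append(classify_behavior(corr.speed_through_water, resting_threshold))
    for k, vals in cols.items():
        track[k] = vals
    track["current_missing"] = missing
    track["behavior"] = behavior
    return track
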