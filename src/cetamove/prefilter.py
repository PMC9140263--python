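"""Outlier removal for raw Argos fixes before state-space modelling.

Argos positions of low quality classes can be tens of kilometres off.  Before
fitting a movement model the raw fixes are screened with a speed/distance/
angle filter: class-Z (invalid) fixes are dropped outright, then fixes whose
implied transit speeds both in and out exceed a ceiling (default 9 m/s, well
above any sustained humpback swim speed) are removed iteratively, and finally
"spikes" — near-out-and-back excursions with long legs and a sharp turning
angle — are removed.  Speeds are computed on WGS84 geodesic distances so the
filter behaves identically at 70°N and at 20°N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geodesy import AzimuthalEquidistant, geodesic_inverse
from .io_formats import ArgosObservation, QUALITY_ORDER


@dataclass
class FilterSettings:
    """Settings for the speed/distance/angle prefilter.

    ``spike_angles`` / ``spike_distances`` are paired: a fix is a spike if its
    turning angle is below ``spike_angles[k]`` while both adjacent legs exceed
    ``spike_distances[k]`` metres, for any k.
    """

    vmax: float = 9.0                                  # m/s
    spike_angles: tuple[float, ...] = (15.0, 25.0)     # degrees
    spike_distances: tuple[float, ...] = (2500.0, 5000.0)  # metres
    drop_classes: frozenset = frozenset({"Z"})

    def __post_init__(self):
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")
        if len(self.spike_angles) != len(self.spike_distances):
            raise ValueError("spike angle and distance lists must pair up")


@dataclass
class Removal:
    index: int           # index into the input observation list
    timestamp: object
    reason: str


@dataclass
class FilterReport:
    n_input: int
    removals: list[Removal] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - len(self.removals)


class InsufficientDataError(ValueError):
    pass


def project_azimuthal_equidistant(obs, center):
    """Project observations to planar metres about ``center=(lon, lat)``.

    Returns parallel lists of (x, y).  Distance from the centre is preserved
    exactly (property of the azimuthal equidistant projection).
    """
    proj = AzimuthalEquidistant(*center)
    xs, ys = [], []
    for o in obs:
        x, y = proj.forward(o.lon, o.lat)
        xs.append(x)
        ys.append(y)
    return xs, ys


def _leg(a: ArgosObservation, b: ArgosObservation):
    """(distance m, speed m/s) of the leg a->b; inf speed for dt <= 0."""
    d, _ = geodesic_inverse(a.lon, a.lat, b.lon, b.lat)
    dt = (b.timestamp - a.timestamp).total_seconds()
    return d, (d / dt if dt > 0 else float("inf"))


def _pick_removal(candidates, obs):
    """Deterministic tie-break: worst quality class first, then latest fix."""
    return max(candidates, key=lambda i: (QUALITY_ORDER.index(obs[i].quality_class),
                                          obs[i].timestamp))


def speed_outliers(kept: list[int], obs, vmax: float) -> list[int]:
    """Indices (into ``obs``) currently implicated by the speed criterion.

    An interior fix is implicated when the speeds of both adjacent legs exceed
    vmax; a terminal fix when its single adjacent leg does.
    """
    out = []
    n = len(kept)
    if n < 2:
        return out
    speeds = []
    for j in range(n - 1):
        _, v = _leg(obs[kept[j]], obs[kept[j + 1]])
        speeds.append(v)
    for j in range(n):
        if 0 < j < n - 1:
            if speeds[j - 1] > vmax and speeds[j] > vmax:
                out.append(kept[j])
        elif j == 0:
            # endpoint implicated only if its leg is fast and the neighbour is
            # not itself an interior outlier (otherwise removing the neighbour
            # fixes both legs)
            if speeds[0] > vmax and not (n > 2 and speeds[1] > vmax):
                out.append(kept[0])
        else:
            if speeds[-1] > vmax and not (n > 2 and speeds[-2] > vmax):
                out.append(kept[-1])
    return out


def _turning_angle(a, b, c) -> float:
    """Angle at b (degrees, 0..180) between legs b->a and b->c on the sphere.

    Computed from geodesic azimuths at b; 0° means a perfect out-and-back.
    """
    _, az_ba = geodesic_inverse(b.lon, b.lat, a.lon, a.lat)
    _, az_bc = geodesic_inverse(b.lon, b.lat, c.lon, c.lat)
    ang = abs(az_ba - az_bc) % 360.0
    return min(ang, 360.0 - ang)


def sda_filter(obs: list[ArgosObservation], settings: FilterSettings | None = None):
    """Speed/distance/angle filter (Freitas-style) on time-sorted fixes.

    Returns ``(kept_observations, FilterReport)``.  The output is a
    subsequence of the input.  Class-Z fixes are removed first, then speed
    outliers iteratively (ties broken toward the worse quality class, then
    the later fix), then distance/angle spikes.
    """
    settings = settings or FilterSettings()
    if any(obs[i].timestamp > obs[i + 1].timestamp for i in range(len(obs) - 1)):
        raise ValueError("observations must be time-sorted")

    report = FilterReport(n_input=len(obs))
    kept = []
    for i, o in enumerate(obs):
        if o.quality_class in settings.drop_classes:
            report.removals.append(Removal(i, o.timestamp, f"class {o.quality_class}"))
        else:
            kept.append(i)

    if len(kept) < 3:
        raise InsufficientDataError(
            f"only {len(kept)} usable fixes after class filtering (need >= 3)"
        )

    # iterative speed criterion
    while True:
        cands = speed_outliers(kept, obs, settings.vmax)
        if not cands:
            break
        worst = _pick_removal(cands, obs)
        report.removals.append(Removal(worst, obs[worst].timestamp, "speed > vmax"))
        kept.remove(worst)
        if len(kept) < 2:
            break

    # iterative distance/angle spikes
    changed = True
    while changed and len(kept) >= 3:
        changed = False
        for j in range(1, len(kept) - 1):
            a, b, c = obs[kept[j - 1]], obs[kept[j]], obs[kept[j + 1]]
            d_in, _ = _leg(a, b)
            d_out, _ = _leg(b, c)
            ang = _turning_angle(a, b, c)
            for amax, dmin in zip(settings.spike_angles, settings.spike_distances):
                if ang < amax and d_in > dmin and d_out > dmin:
                    report.removals.append(
                        Removal(kept[j], b.timestamp,
                                f"spike (angle {ang:.1f} deg, legs > {dmin:.0f} m)")
                    )
                    kept.pop(j)
                    changed = True
                    break
            if changed:
                break

    return [obs[i] for i in kept], report
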