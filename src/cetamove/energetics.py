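"""Drag-based bioenergetic budget for a migrating whale.

Two components are summed:

* **Maintenance** — basal metabolism from the Kleiber allometric law,
  ``BMR = 70 * M^0.75`` kcal/day, converted to joules (4186.8 J/kcal).  For a
  30,000 kg humpback female this is ~668.5 MJ/day, accrued per 6-hour step so
  that budgets add exactly over windows.
* **Cost of transport (E_COT)** — the power needed to overcome hydrodynamic
  drag at swim speed ``V``,

      P = (lambda / (2 eps_A eps_P)) * rho * S * C_d * V^3   [W],

  where ``S = a M^b`` is the wetted surface area, ``eps_A``/``eps_P`` the
  aerobic and propulsive efficiencies, ``lambda`` the active-to-passive drag
  ratio and ``rho`` seawater density.  Step energy is power times the step
  duration; daily cost sums four 6-hour steps.

Costs of gestation and lactation are deliberately not modelled, so totals for
a pregnant/lactating female are underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

KCAL_TO_J = 4186.8
KLEIBER_COEF = 70.0          # kcal / (day * kg^0.75)


@dataclass(frozen=True)
class BioenergeticParams:
    """All symbols of the maintenance and drag equations.

    The wetted surface ``S`` is derived from mass via ``S = a * M**b`` and is
    recomputed automatically whenever the mass changes (it is a property).
    """

    mass_kg: float = 30000.0
    drag_coefficient: float = 0.003
    surface_coef_a: float = 0.054
    surface_coef_b: float = 0.696
    propulsive_efficiency: float = 0.8
    aerobic_efficiency: float = 0.2
    drag_ratio: float = 0.7          # active : passive drag
    seawater_density: float = 1027.0  # kg/m^3

    def __post_init__(self):
        for name in ("mass_kg", "drag_coefficient", "surface_coef_a",
                     "surface_coef_b", "drag_ratio", "seawater_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("propulsive_efficiency", "aerobic_efficiency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def wetted_surface_m2(self) -> float:
        return self.surface_coef_a * self.mass_kg**self.surface_coef_b

    def with_mass(self, mass_kg: float) -> "BioenergeticParams":
        return replace(self, mass_kg=mass_kg)


def bmr_daily(params: BioenergeticParams = BioenergeticParams()) -> float:
    """Basal metabolic rate in MJ/day (Kleiber law, kcal converted to J)."""
    if params.mass_kg <= 0:
        raise ValueError("mass must be positive")
    return KLEIBER_COEF * params.mass_kg**0.75 * KCAL_TO_J / 1e6


def cot_power(V, params: BioenergeticParams = BioenergeticParams()):
    """Instantaneous power (W) to overcome drag at swim speed V (m/s)."""
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("swim speed cannot be negative")
    coef = (params.drag_ratio
            / (2.0 * params.aerobic_efficiency * params.propulsive_efficiency))
    P = coef * params.seawater_density * params.wetted_surface_m2 \
        * params.drag_coefficient * V**3
    return float(P) if P.ndim == 0 else P


def step_cot_energy(V, dt_s, params: BioenergeticParams = BioenergeticParams()):
    """Energy (J) to swim at speed V for dt_s seconds."""
    if np.any(np.asarray(dt_s) <= 0):
        raise ValueError("step duration must be positive")
    return cot_power(V, params) * dt_s


@dataclass
class EnergyBudget:
    """Per-window energetic budget (the shape of a cost-of-migration table)."""

    days: float
    transit_days: float
    stationary_days: float
    distance_km: float
    median_speed: float
    speed_iqr: tuple[float, float]
    e_cot_mj: float
    maintenance_mj: float

    @property
    def e_total_mj(self) -> float:
        return self.e_cot_mj + self.maintenance_mj

    @property
    def e_per_day_mj(self) -> float:
        """Total energy divided by window days."""
        return self.e_total_mj / self.days if self.days > 0 else float("nan")

    @property
    def e_per_day_mean_of_daily_mj(self) -> float:
        """Alternative per-day figure: mean of whole-day totals (set by budget)."""
        return getattr(self, "_mean_daily", self.e_per_day_mj)

    def summary(self) -> str:
        q25, q75 = self.speed_iqr
        return "\n".join([
            "Energetic cost of migration window",
            "=" * 36,
            f"duration (days):        {self.days:.2f} "
            f"(transiting: {self.transit_days:.2f}, "
            f"stationary: {self.stationary_days:.2f})",
            f"distance (km):          {self.distance_km:.0f}",
            f"median swim speed:      {self.median_speed:.2f} m/s "
            f"(Q25-Q75: {q25:.2f}-{q75:.2f})",
            f"E_COT (MJ):             {self.e_cot_mj:.0f}",
            f"maintenance (MJ):       {self.maintenance_mj:.0f}",
            f"E_total (MJ):           {self.e_total_mj:.0f}",
            f"E per day (MJ/day):     {self.e_per_day_mj:.1f}",
            "(gestation and lactation costs are not included; totals are "
            "underestimates for a pregnant or lactating female)",
        ])

    def to_dict(self) -> dict:
        return {
            "days": self.days,
            "transit_days": self.transit_days,
            "stationary_days": self.stationary_days,
            "distance_km": self.distance_km,
            "median_speed_ms": self.median_speed,
            "speed_q25": self.speed_iqr[0],
            "speed_q75": self.speed_iqr[1],
            "e_cot_mj": self.e_cot_mj,
            "maintenance_mj": self.maintenance_mj,
            "e_total_mj": self.e_total_mj,
            "e_per_day_mj": self.e_per_day_mj,
        }


def budget(track: pd.DataFrame, params: BioenergeticParams = BioenergeticParams(),
           window=None, resting_threshold: float = 0.5,
           max_missing_fraction: float = 0.05) -> EnergyBudget:
    """Energy budget over a window of a regular predicted track.

    ``track`` must carry timestamp, a swim-speed column
    (``speed_through_water``, else ``speed_over_ground``) and, if available,
    ``step_distance_m``.  ``window`` is an optional ``(start, end)`` timestamp
    pair (end exclusive); maintenance accrues per step (BMR / steps-per-day)
    so that budgets over disjoint adjacent windows sum exactly.
    """
    ts = pd.to_datetime(track["timestamp"])
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        sel = (ts >= lo) & (ts < hi)
        track = track.loc[sel].reset_index(drop=True)
        ts = ts[sel].reset_index(drop=True)
    if len(track) == 0:
        raise ValueError("window contains no steps")

    col = "speed_through_water" if "speed_through_water" in track.columns \
        else "speed_over_ground"
    V = track[col].to_numpy(dtype=float)
    n_missing = int(np.sum(~np.isfinite(V)))
    if n_missing > max_missing_fraction * len(V):
        bad = ts[~np.isfinite(V)].tolist()
        raise ValueError(f"swim speed missing for {n_missing} steps: {bad[:5]}...")
    V = np.nan_to_num(V, nan=0.0)

    if len(ts) > 1:
        dt_s = float((ts.iloc[1] - ts.iloc[0]).total_seconds())
    else:
        dt_s = 6 * 3600.0
    days = len(track) * dt_s / 86400.0

    transiting = V > resting_threshold
    transit_days = float(np.sum(transiting)) * dt_s / 86400.0

    if "step_distance_m" in track.columns:
        dist_km = float(np.nansum(track["step_distance_m"].to_numpy()) / 1000.0)
    else:
        dist_km = float(np.sum(V * dt_s) / 1000.0)

    e_cot = float(np.sum(step_cot_energy(V, dt_s, params)) / 1e6)
    maint = bmr_daily(params) * days

    vt = V[transiting] if transiting.any() else V
    b = EnergyBudget(
        days=days,
        transit_days=transit_days,
        stationary_days=days - transit_days,
        distance_km=dist_km,
        median_speed=float(np.median(V)),
        speed_iqr=(float(np.quantile(V, 0.25)), float(np.quantile(V, 0.75))),
        e_cot_mj=e_cot,
        maintenance_mj=maint,
    )
    # secondary per-day definition: mean over whole UTC days of daily totals
    day_keys = ts.dt.floor("D")
    per_day = pd.Series(step_cot_energy(V, dt_s, params) / 1e6).groupby(
        day_keys.values).sum() + bmr_daily(params) * dt_s / 86400.0 * \
        pd.Series(np.ones(len(V))).groupby(day_keys.values).sum()
    b._mean_daily = float(per_day.mean())
    b.median_transit_speed = float(np.median(V[transiting])) if transiting.any() \
        else float("nan")
    return b


@dataclass
class Scenario:
    speed: float
    duration_days: float
    delay_days: float
    e_cot_mj: float
    maintenance_mj: float

    @property
    def e_total_mj(self) -> float:
        return self.e_cot_mj + self.maintenance_mj


def scenario_sweep(distance_km: float, speeds,
                   params: BioenergeticParams = BioenergeticParams(),
                   reference_duration_days: float | None = None,
                   reference_speed: float | None = None) -> list[Scenario]:
    """Theoretical budgets for covering a distance at constant alternative speeds.

    For each speed: duration = distance / speed, constant-speed E_COT over
    that duration, maintenance over that duration, and the delay relative to
    the reference (an observed duration in days, or a reference speed).
    """
    if distance_km <= 0 or any(s <= 0 for s in speeds):
        raise ValueError("distance and speeds must be positive")
    if reference_duration_days is None:
        if reference_speed is None:
            raise ValueError("give a reference duration or reference speed")
        reference_duration_days = distance_km * 1000.0 / reference_speed / 86400.0
    out = []
    for s in speeds:
        dur_s = distance_km * 1000.0 / s
        dur_days = dur_s / 86400.0
        out.append(Scenario(
            speed=s,
            duration_days=dur_days,
            delay_days=dur_days - reference_duration_days,
            e_cot_mj=float(cot_power(s, params) * dur_s / 1e6),
            maintenance_mj=bmr_daily(params) * dur_days,
        ))
    return out


def scenario_table(scenarios: list[Scenario]) -> pd.DataFrame:
    return pd.DataFrame([{
        "speed_ms": s.speed,
        "duration_days": s.duration_days,
        "delay_days": s.delay_days,
        "e_cot_mj": s.e_cot_mj,
        "maintenance_mj": s.maintenance_mj,
        "e_total_mj": s.e_total_mj,
    } for s in scenarios])
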