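# cetamove

Satellite-telemetry analysis for migrating whales: Argos track filtering,
state-space track reconstruction, behavioural segmentation, ocean-current
correction, and a drag-based energy budget — the full computational chain
needed to turn a year of raw Argos fixes from a single animal into migration
phases, a calving date, and the energetic cost of the migration. A
synthetic-data generator with known ground truth makes every stage testable
without any external data products.

Intended users: movement ecologists and bioenergetics modellers working with
Argos-tracked large whales (or any marine megafauna with similar data).

## The models

**Track reconstruction.** Raw Argos fixes are irregular in time and carry
anisotropic errors (the CLS error ellipse, up to kilometres for classes A/B).
After a speed/distance/angle prefilter (max speed 9 m/s; class-Z fixes
dropped), the track is modelled as a continuous-time correlated random walk:
per planar axis an integrated Ornstein–Uhlenbeck velocity

dv = −β v dt + σ dW,   x(t) = ∫ v,

discretised exactly between fix times and observed through each fix's
ellipse covariance. `CrwModel.fit()` maximises the exact Kalman-filter
likelihood over (β, τ = σ/√(2β), ψ), where ψ is a global error-ellipse
inflation; `CrwResults.predict(6)` returns the smoothed state at regular
6-hour steps.

**Movement persistence.** Behaviour is summarised by γ ∈ [0, 1], the
autocorrelation of successive displacements d_t = γ_t d_{t−1} + ε_t with
logit(γ_t) a Gaussian random walk — γ ≈ 0 is area-restricted search, γ ≈ 1
directed transit. Estimated by penalised likelihood (banded Newton), with the
smoothness chosen by Laplace marginal likelihood.

**Segmentation.** Changes in the mean of γ (migration phases) or of swim
speed (calving) are found by exact dynamic-programming minimisation of the
within-segment sum of squares, with the number of segments chosen by the
penalised threshold rule (S = 0.75) or fixed by the analyst.

**Currents and swim speed.** Surface currents (u, v) are sampled
nearest-in-time-then-space from a gridded field; the swim vector is the
ground vector minus the current, giving speed through water V, with
along-track (support) and cross-track components. V ≤ 0.5 m/s is classed as
resting.

**Energy budget.** Maintenance follows Kleiber, BMR = 70 M^0.75 kcal/day
(×4186.8 J/kcal): ≈ 668.5 MJ/day at M = 30,000 kg. Swimming adds the power
to overcome drag,

P = λ/(2 ε_A ε_P) · ρ S C_d V³,

with S = 0.054 M^0.696 m² wetted area, C_d = 0.003, ε_P = 0.8, ε_A = 0.2,
λ = 0.7, ρ = 1027 kg/m³ — about 475 W at 1 m/s, cubing with speed. Step
energies (power × 6 h) and per-step maintenance accrual sum exactly over any
window. Gestation and lactation are not modelled; totals for a breeding
female are underestimates.

**Routes.** WGS84 geodesic distances, and shortest paths through water on a
bathymetry grid (cells deeper than 10 m, 16-connected with geodesic edge
weights, exact Dijkstra) for comparing observed routes to the shortest
possible ones.

## Worked example

```python
import numpy as np
from cetamove import synthdata
from cetamove.io_formats import RunConfig
from cetamove.pipeline import run_pipeline

spec = synthdata.paper_like_scenario(seed=1)        # 321-day deployment
field = synthdata.make_current_field(spec)
truth = synthdata.simulate_truth(spec, current_field=field)
obs = synthdata.observe_argos(truth, spec)          # ~4,500 Argos-like fixes

res = run_pipeline(obs, "run1", RunConfig(seed=1),
                   current_field=field, n_phases=7, log=lambda m: None)
print(res.budgets["migration"].summary())
```

prints (seed 1):

```
Energetic cost of migration window
====================================
duration (days):        170.75 (transiting: 150.75, stationary: 20.00)
distance (km):          18821
median swim speed:      1.36 m/s (Q25-Q75: 0.94-1.70)
E_COT (MJ):             23637
maintenance (MJ):       114073
E_total (MJ):           137710
E per day (MJ/day):     806.5
(gestation and lactation costs are not included; totals are underestimates
for a pregnant or lactating female)
```

The 170-day migration window, ~18,800 km of track, a median transit speed
near 1.4 m/s, and a total cost of ~138 GJ split roughly 1:5 between drag and
maintenance are the quantities of interest; `res.phases` carries the seven
dated movement phases and `res.calving` the detected speed breakpoint
(here 1.70 → 1.28 m/s, within 6 hours of the planted event).

The same stages are available from a shell:

```bash
cetamove synth --seed 1 --out demo/
cetamove pipeline demo/argos.csv --currents demo/currents.nc --out demo/run/
```

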