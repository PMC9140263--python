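# Methods

This note documents the models implemented in `cetamove`, the choices made
where the design was genuinely open, the calibration of the synthetic-data
generator, and the limits of what the test suite demonstrates.

## Prefilter

Class-Z (invalid) fixes are removed first. The speed criterion is applied
iteratively: an interior fix is implicated when the implied transit speed
both into and out of it exceeds `vmax` (default 9 m/s, far above sustained
humpback swimming); a terminal fix when its single adjacent leg does and its
neighbour is not itself implicated. One fix is removed per iteration — the
worst Argos class among those implicated, latest fix on ties — so the result
is deterministic. Distance/angle "spikes" (turning angle below 15°/25° with
both legs beyond 2.5/5 km) are removed afterwards. All speeds and angles use
WGS84 geodesics, so behaviour is identical at 70°N and 20°N. The filter is
idempotent and its output is a subsequence of its input; both are property
tests, and the speed criterion is checked against an independently coded
brute-force restatement.

## Continuous-time correlated random walk

State per planar axis: position and an Ornstein–Uhlenbeck velocity with
reversion rate β (1/s) and stationary SD τ (m/s). The transition over an
arbitrary gap Δt is exact:

- velocity: v' = φ v + N(0, τ²(1−φ²)), φ = e^{−βΔt}
- position gains (1−φ)/β · v plus correlated noise with
  Var = σ²/β² (Δt − 2(1−φ)/β + (1−φ²)/(2β)), Cov = σ²(1−φ)²/(2β²),
  σ² = 2βτ².

Each fix is observed through its error-ellipse covariance (variances are the
squared semi-axes; the major axis points `orientation` degrees clockwise
from north). Fixes without ellipses use class-based isotropic SDs
(3: 250 m, 2: 500 m, 1: 1.5 km, 0: 4 km, A: 6 km, B: 10 km), a deliberately
conservative table for legacy exports. The likelihood is the exact Kalman
prediction-error decomposition; optimisation runs Nelder–Mead on
(log β, log τ[, log ψ]) from three documented starts (velocity time scales
of 1, 6 and 24 h at the empirical displacement speed scale), best likelihood
wins. ψ is a global multiplier on all ellipse covariances: reported ellipses
are trusted up to scale, absorbing both ellipse miscalibration and movement
that a single-regime CTCRW cannot represent. The pipeline estimates ψ by
default. Standard errors come from the numerical observed information on the
log scale.

Smoothing is Rauch–Tung–Striebel; regular-interval prediction inserts the
6-hour grid as missing observations. The smoother is verified against an
independent joint-Gaussian-conditioning oracle to 10⁻⁶ m on small instances,
and simulation-based parameter recovery is checked by 95 % CI coverage over
20 replicates. The Kalman recursions are JIT-compiled with numba when
available, with a transparent pure-Python fallback.

`speed_over_ground` at step i is the geodesic displacement to step i+1
divided by the interval; the final step repeats the preceding value.

## Movement persistence

γ_t is the coefficient in d_t = γ_t d_{t−1} + ε_t, ε ~ N(0, σ² I₂), on the
regular 6-hour displacements, with logit(γ_t) a Gaussian random walk of step
SD σ_g. The posterior mode of the logit path is found by a banded
Gauss–Newton iteration (tridiagonal Hessian, backtracking line search,
logits clipped to ±9); σ is profiled; σ_g is selected from
{0.05, 0.1, 0.2, 0.4, 0.8, 1.6} by a Laplace-approximate marginal
likelihood. The profiled σ² keeps a relative floor (10⁻⁸ of the mean squared
displacement) so noiseless tracks remain well conditioned. γ for the first
two track points repeats the first estimable state.

Known bias: the model assumes one residual scale for the whole track. When a
track mixes fast directed transit with slow residency, the shared σ and the
smoothing both pull residence-phase γ upward (see Limitations).

## Segmentation

The mean-change contrast (within-segment sum of squared deviations) is
minimised exactly by dynamic programming over all segmentations with
segments of at least `Lmin` points (default 8 = 2 days, suppressing
single-fix artifacts). The number of segments uses the penalised threshold
rule: with J(K) normalised to [1, Kmax], the chosen K is the largest whose
second difference D(K) exceeds S = 0.75, ties to smaller K. Two additions:

- a noise guard returns K = 1 unless segmenting explains more than
  ~6(Kmax−1)/n of the total contrast (the measured size of spurious drops on
  white noise), and
- `detect_migration_phases(K=...)` fixes the segment count, the workflow in
  which the analyst reads K off the contrast curve. The threshold rule is
  conservative when short stopovers are embedded in long residencies — the
  second differences it thresholds are small even on noise-free series — so
  the end-to-end analyses in this package fix K at the known/published
  segment count.

Segments are labelled transit when their mean γ is at or above the track
median (≥ 0.5 for a single segment), residence otherwise. Calving detection
is the exact K = 2 segmentation of the swim-speed series of the final
southbound transit; if splitting reduces the contrast by under 5 % the
result is "no change detected". DP optimality is verified against exhaustive
enumeration for n ≤ 30, K ≤ 3.

## Currents and speed through water

Current sampling is nearest in time (ties to the earlier record), then
nearest cell (ties to the lower index); masked cells fall back to the
nearest valid cell within 3 rings, recording the fallback distance, else the
step is flagged and treated as zero current. The current is sampled at each
step's start and held constant over the step. Correction is vector
subtraction: swim = ground/Δt − (u, v); support is the current component
along the track direction, cross the component 90° counterclockwise of it
(positive pushes left of travel). Zero ground displacement with nonzero
current yields V = |current| with support 0, flagged. Correction exactly
inverts simulated advection (10⁻⁹ property test). Surface (0–5 m) currents
stand in for swim-depth currents.

## Energetics

Maintenance: 70 M^0.75 kcal/day × 4186.8 J/kcal, accrued per 6-hour step
(BMR/4) so budgets over adjacent windows add exactly. Cost of transport:
P = λ/(2 ε_A ε_P) ρ S C_d V³ per step times 21,600 s; daily costs sum four
steps. Parameter defaults (M = 30,000 kg, C_d = 0.003, S = 0.054 M^0.696,
ε_P = 0.8, ε_A = 0.2, λ = 0.7, ρ = 1027 kg/m³) are the values used for
humpback-scale bioenergetics in the tracking literature; all are overridable
and S tracks M. Two per-day figures are exposed (window total ÷ days, and
the mean of whole-UTC-day totals) because the aggregation behind published
per-day numbers is ambiguous. Gestation and lactation are excluded, and the
reports say so: totals for a breeding female are lower bounds. The scenario
sweep takes the reference as an observed duration (or speed); delays are
durations at the alternative speed minus the reference duration.

## Routes

Water cells are those deeper than `min_depth` (default 10 m). The graph is
16-connected (8 neighbours + knight moves, reducing grid-direction bias;
8-connectivity by flag) with WGS84 geodesic edge lengths; knight moves
additionally require one of the two intermediate cells to be water, so paths
cannot hop single-cell land walls. Endpoints snap to the nearest admissible
cell within 5 cells. Dijkstra (scipy.sparse.csgraph) gives the exact graph
optimum, verified against an independent exhaustive search with admissible
pruning on 6×6 grids. Raising `min_depth` never shortens a path (property
test).

## Synthetic-data generator

The default scenario is a 321-day, seven-phase round-trip at the scales of a
full Northeast Atlantic migration: a 30-day feeding residence, a 7-day
transit at 1.9 m/s, a 15-day stopover, a 61-day southbound transit at
1.7 m/s with a calving event 24 days in (one near-stationary day at 0.3 m/s,
then 1.3 m/s), a 16-day breeding residence, a 71-day northbound transit at
1.5 m/s, and a final feeding residence — ~170 migration days and ~19,000 km
of track. Residence persistence is 0.1 (deep area-restricted search),
transit persistence 0.9.

Velocities follow a per-phase AR(1) with drift set by the phase heading.
Three calibration devices make the ground truth exact rather than
approximate: innovations are centred within each behavioural unit, the mean
velocity is pinned to the drift (equivalent to the same AR model with an
adjusted drift), and the speed profile is rescaled so the realised mean
speed equals the target. Argos-like fixes arrive as a Poisson process
(14/day), with classes drawn from a fixed mix (10/15/20/20/20/15 % for
3/2/1/0/A/B), error ellipses at Kalman-processed CLS magnitudes
(0.25–4.5 km semi-major by class), 2 % gross outliers (60–250 km) and 1 %
class-Z rows. The toy current field derives from a doubly periodic
streamfunction by central differences on a uniform nominal metric, making
the same central-difference divergence vanish identically; tracks are
advected by it when supplied. The depth grid is constant-depth ocean with
polygon land masses. One seed drives three independent sub-streams (truth,
observation, fields).

What the generator does **not** emulate: real coastline geometry, tidal or
depth-varying currents, duty-cycled transmission gaps, fix-quality
correlation with behaviour (whales surface differently when travelling), or
projection-convergence effects (the planar axes are treated as east/north
for both advection and correction, consistently on both sides). Passing
tests therefore show the chain is correct and well calibrated under these
idealisations, not that field data will behave as cleanly.

## Problem sizes

Unit tests run on short tracks (tens to hundreds of steps) and small grids;
the end-to-end analyses use the full 321-day scenario (~4,500 fixes, 1,284
steps) over five replicate seeds, which keeps the whole suite to a few
minutes on one core.

## Limitations

- **Residence persistence is over-estimated under realistic Argos noise.**
  Smoothing (CTCRW + penalised persistence) correlates successive estimated
  displacements; slow-movement phases come out at γ ≈ 0.3–0.5 when the
  truth is 0.1, while transits are essentially unbiased. On noise-free
  tracks the bias disappears, so it is an observation-noise × smoothing
  effect intrinsic to this model chain at 6-hour resolution.
- **Phase starts are detected early.** Residence→transit boundaries are
  placed ~2–9 steps (up to ~2 days) before the true departure: residence
  displacements carry little weight in the persistence likelihood, so the
  directed regime bleeds backwards. Transit→residence boundaries are
  accurate to ±2 steps.
- **Calving localisation depends on the speed wander.** With realistic
  autocorrelated swim-speed fluctuation (CV 0.3, days-scale memory) the
  within-leg wander occasionally rivals the 0.4 m/s calving shift and the
  mean-change optimum locks onto a wander edge; across replicate
  deployments, recovery ranges from six hours to ~2 weeks. The recovered
  pre/post median speeds are accurate throughout.
- **Energy totals are robust.** Because E_COT integrates V³ over ~680
  steps, local errors average out: migration-window E_COT lands within a
  few percent of the truth-speed value in essentially all replicates, and
  the maintenance term is exact by construction.
- The single-regime CTCRW and the homoscedastic persistence model are the
  standard field tools and are kept deliberately; regime-switching movement
  models would likely reduce the first two limitations at the cost of a
  different model class.
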