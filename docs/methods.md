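# Methods

## Model family

The package treats tumor growth as the two-exponent family

dv/dt = p·v^a − q·v^b,  v(t₁) = v₀ > 0,  0 ≤ a < b,

with v in mm³ and t in days. Every exponent pair (a, b) is a separate
three-parameter model (p, q, v₀); the pair itself is selected by grid
search, never by continuous optimization. The diagonal a = b is
excluded: those limits obey a different (Gompertz-type) equation and are
out of scope. For p, q, v₀ > 0 every trajectory is monotone toward the
globally attracting equilibrium K = (p/q)^(1/(b−a)) (the asymptotic
volume); for a > 0 the growth rate peaks at the inflection volume
(a·p/(b·q))^(1/(b−a)) < K. Closed forms exist for the pairs (1, 2)
(logistic) and (0, 1) (bounded exponential); they are used as oracles
for the numeric integrator, not as computational paths.

Assumptions inherited from the least-squares objective: additive,
homoscedastic, independent Gaussian measurement error on volumes. The
residual report (sign test, composite Anderson–Darling and Cramér–von
Mises) exists to check exactly this assumption. A multiplicative
(lognormal) error variant is deliberately not implemented.

## Numerical integration

Curves are integrated in log volume, u = ln v, where
du/dt = p·e^{(a−1)u} − q·e^{(b−1)u}. This preserves positivity and keeps
the b-term conditioned in the extreme fitted regimes (b ≈ 9–10 forces
q ≈ 1e−29…1e−34; in raw volume the term q·v^b overflows double
precision routinely). The integrator is an adaptive Dormand–Prince 5(4)
scheme compiled with numba (`_core.integrate_log`), with:

* tolerances rtol = 1e−8, atol = 1e−10 in u (configurable at the
  `solve_curve` level);
* an analytic equilibrium shortcut: the equation is autonomous and
  scalar with the single attractor u* = (ln p − ln q)/(b − a), so once
  |u − u*| falls below twice the local error tolerance the remaining
  outputs are set to u*. Without this, an explicit scheme crawls at the
  stability limit for stiff relaxation rates (|g′(u*)| up to 10²–10³
  per day) and dominates runtime;
* hard failure sentinels instead of silent garbage: |u| > 200, a
  non-finite state, or more than 5,000 steps per solve marks the
  remainder of the trajectory NaN, which the fitting layer scores as
  SSE = +inf (always rejected) and the public `solve_curve` raises as
  `CurveSolutionError`.

scipy's stiff-switching LSODA on the same log-space equation is kept as
an independent cross-check path (`solve_curve(..., method="lsoda")`);
the two paths agree to ~1e−8 relative on all regimes tested, including
(1.34, 8.83). The compiled path exists because the annealer needs
10⁵–10⁶ curve solves per exponent pair (~7 µs each, vs ~1 ms per scipy
call).

## Optimization per exponent pair

SSE is minimized over (ln p, ln q, ln v₀) in two stages.

**Annealing (global stage).** A custom simulated-annealing variant:
each proposal multiplies all three parameters by positive factors
exp(σZ), Z ~ N(0,1) — scale-free steps, essential when q ranges over 30
orders of magnitude. Downhill moves are always accepted; uphill moves
with Metropolis probability exp(−ΔSSE/T). Every 1,000 steps the chain
restarts from the best point seen so far. The temperature is written
T = c·(best SSE so far): tying T to the best-seen SSE makes the
schedule track the objective scale, which falls by ~3 orders of
magnitude during a cold fit — a temperature cooled only by fixed
factors from its initial calibration cannot span that range within the
step budget. The coefficient c is calibrated from the first 100
proposals (so that the mean observed uphill move would be accepted with
probability 0.3) and cooled at each restart: ×0.9 if the recent
uphill-acceptance rate exceeded 20%, ×0.97 otherwise. SSE ties update
the best-seen *point* (not just the value), so diffusion across flat
plateaus is not undone by restarts.

Cold starts use p = q = 1, v₀ = v₁ (the first observed volume) and
50,000 steps; warm starts (from a neighboring pair's optimum during grid
sweeps) use 10,000. Defaults that are this package's own calibration,
measured on the built-in dataset:

* **σ = 0.2.** The cold-start landscape contains a strong spurious
  basin in which the curve jumps almost instantly to its asymptote
  (SSE flat in p); escaping it requires ln p to drift ~7–8 units. With
  σ = 0.05 the walk's per-restart-interval reach (~√1000·σ) is ~1.6
  units and every tested seed stays trapped; σ ≥ 0.2 escapes reliably
  while exp(0.2·Z) still keeps proposal factors close to 1.
* **Four independent cold chains**, the raw seed first, then derived
  seeds with σ escalated ×1/×2/×2/×4; the best chain wins. Single
  σ = 0.2 chains still fail on a sizeable fraction of seeds for some
  datasets (measured ~50% on a noiseless synthetic copy of the best-fit
  curve; ~10% at σ = 0.4); the escalating ensemble drove the failure
  rate to 0/20 seeds on every case measured. Warm starts use one chain.

**Polish (local stage).** scipy `least_squares` (trust-region
reflective, finite-difference Jacobian) on the same log parameters,
tolerances 1e−14, at most 400 residual evaluations. Positivity is
implicit in the parameterization. The polished result is kept only if
it does not increase SSE. On the built-in data the polish improves the
annealed optimum by less than the displayed precision, as expected for
a converged anneal.

**Ladder fits.** Pairs with b far above a (the 107-day segment optimum
(1.34, 8.83) needs q ≈ 2e−29) are unreachable by any cold chain: ln q
must travel ~66 units. `ladder_fit` reproduces the mechanism that makes
such pairs reachable in the grid sweep — warm-starting each fit from
the optimum at the previous, smaller b — as a standalone ladder with
default rung 0.5 in b. This is the supported way to fit a single
large-gap pair.

## Grid sweep, extension, regions

The sweep covers a = m·s, b = a + n·s (default s = 0.01; the bundled
analyses and tests use s = 0.1 for tractability — a full 0.01 sweep of
the default rectangle is ~45,000 fits and is CPU-days territory). The
outer loop runs over a; within a row the near-diagonal pair is fitted
cold and subsequent pairs warm-start from their left neighbor. Per-pair
seeds are derived from the run seed and the pair indices, so results are
independent of execution order and bit-reproducible.

The default initial search rectangle is 0 ≤ a ≤ 2.1, a < b ≤ 3.1 —
covering all named models and their surroundings; it is configurable.
If the best pair lies on the grid's upper (max-b) or right (max-a)
boundary, the grid is extended by 0.5 in that direction and the new
pairs fitted (warm from the rightmost existing fit of each row), until
the optimum is interior or the caps (a ≤ 4, b ≤ 12, covering the most
extreme segment optima seen in practice) are reached; hitting a cap
sets `optimality_secured = False` on the landscape.

A smoothness guard mirrors the manual practice of re-running "frayed"
regions: within a, b ≤ 3, an entry whose SSE deviates from the median of
its ≤8 grid neighbors by more than 50% is re-fitted — warm from its best
neighbor's parameters and (first pass) cold with a 5× budget — for up to
three passes. A stuck row head otherwise propagates its basin down the
whole row via the warm starts.

Near-optimal regions are the sub-level sets
{(a, b) : SSE_opt ≤ (1+θ)·min SSE_opt}, θ ∈ {1%, 5%, 10%} by default.
They are nested by construction and always contain the argmin; their
size is the package's measure of model identifiability. Landscape
tables serialize as CSV (`a,b,v0,p,q,sse`) at 17 significant digits so
the tiny q values survive a round trip.

## Prognosis

A segment specification keeps observations with t ≤ cutoff (refusing
segments with fewer than 4 points for a 5-parameter family; default
cutoffs 65/76/87/98/107 days for the built-in series). The segment gets
a full sweep + extension; the best fitted curve is then evaluated,
unchanged, on the complete series (`extrapolation_sse`) — anchoring is
preserved because truncation keeps the first observation. The usable
forecast horizon of a segment fit is the longest time past the cutoff
over which every observed point is predicted within a relative volume
tolerance (default 15%; the threshold is a reporting choice exposed as
a flag, and the horizon is quantized to the observation times). The
cross-segment summary is the median horizon.

## Diagnostics

* Residuals vᵢ − v(tᵢ); SD with denominator n − 1. Sign test: exact
  two-sided binomial on the residual signs (zeros dropped). Normality:
  composite variants with mean and SD estimated from the residuals —
  the only defensible choice for fitted residuals — using statsmodels'
  Anderson–Darling and a seeded parametric bootstrap (default 2,000
  replicates) for the Cramér–von Mises p-value, which no installed
  package exposes in composite form.
* Data spline: natural cubic spline (zero second derivative at the
  ends; "not-a-knot" available), exact at the knots; the model-free
  relative growth rate is s′(t)/s(t), with non-positive spline values
  flagged as NaN gaps.
* Growth-rate envelopes: pointwise min/max of v′/v = p·v^{a−1} − q·v^{b−1}
  across the best-fit curves of all near-optimal pairs; nested in the
  threshold because the model sets are.
* Prediction band: t-based single-observation band,
  v(t) ± t_{1−α/2, n−3} · s · √(1 + h), with s² = SSE/(n − 3) and
  leverage h from the finite-difference Jacobian of the curve with
  respect to the log parameters (central differences, step 1e−5). A
  singular normal matrix drops the leverage term. Parameter confidence
  intervals from the same Jacobian are method-dependent and not part of
  any cross-package comparison here.

## Synthetic data generator

`generate_synthetic(params, times, noise_sd, seed)` samples an exact
model curve and adds independent Gaussian noise, truncating at a small
positive floor (warning if >10% of points truncate). It emulates the
measurement setup of the reference series — n = 14 sparse, strictly
increasing observation times over ~114 days, homoscedastic error; the
recovery experiments use the best-fit curve (a = 1.62, b = 2.44,
p = 5.02e−4, q = 5.55e−7, v₀ = 318.5) as truth with noise SD at 5% of
the maximum volume. What it does not emulate: volume-dependent
(multiplicative) error, serial correlation from repeated measurement of
the same animals, averaging over a treatment group, digitization error,
or outliers. Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not
robustness to real-data pathologies.

## Problem sizes in the bundled tests

The test suite and the acceptance script run the reference step budgets
(50,000/10,000/1,000) for single-pair fits, a spacing-0.1 sweep of the
initial rectangle for landscape-level checks, 20 seeds for the noisy
recovery experiment and 200 replicates for band coverage. These sizes
are the package's chosen defaults for a desk-scale reproduction; a
production 0.01-resolution sweep uses the same code paths unchanged.

## Known limitations

* Global optimality per pair is not guaranteed — the contract is
  monotone improvement, seeded reproducibility, and agreement with the
  published optima on the reference data.
* The explicit integrator handles the family's stiffness through the
  equilibrium shortcut; pathological parameter regions are rejected via
  sentinels rather than integrated exactly.
* Near-optimal region *counts* depend on the exact grid footprint and
  resolution and are not comparable across implementations; region
  geometry (nesting, membership, rank order of sizes) is.
* p-values of the composite normality tests depend on the bootstrap
  variant; they are reported for diagnosis, not inference.
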