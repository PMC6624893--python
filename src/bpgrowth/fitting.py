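"""Least-squares fitting of one exponent pair.

For a fixed (a, b) the free parameters are (p, q, v0) and the objective
is the sum of squared volume errors

    SSE(p, q, v0) = sum_i (v_i - v(t_i))^2 .

The global search is a multiplicative simulated-annealing variant: each
proposal multiplies every parameter by a positive random factor close
to 1, uphill moves are accepted Metropolis-style, the chain restarts
from the best-seen parameters at fixed intervals, and the temperature is
cooled adaptively based on the recent uphill-acceptance rate.  The
annealed optimum is then polished by a deterministic nonlinear
least-squares refinement in log-parameter space.

Standard all-purpose optimizers started from naive initial values fail
on this family — the SSE valley is extremely elongated (p and q trade
off almost exactly when b - a is small) and q spans ~30 orders of
magnitude across exponent pairs — which is why the scale-free
multiplicative walk is used for the global stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from . import _core
from .dataset import GrowthDataset
from .ode import DEFAULT_ATOL, DEFAULT_RTOL, BPParameters, ExponentPair

__all__ = ["AnnealConfig", "FitResult", "sse_of", "anneal_fit",
           "polish_fit", "fit_pair", "ladder_fit"]

_BIG_RESIDUAL = 1e12  # stands in for an infeasible curve inside the polisher

#: proposal-scale multipliers for the successive independent cold chains;
#: hotter chains diffuse farther and escape the spurious fast-dynamics
#: basin more reliably, while chain 0 keeps the configured scale
_CHAIN_SIGMA_FACTORS = (1.0, 2.0, 2.0, 4.0)


@dataclass(frozen=True)
class AnnealConfig:
    """Annealer settings.

    The step budgets mirror the reference protocol: 50,000 steps for a
    cold start at the beginning of a grid row, 10,000 for warm starts
    along the row, and a restart from the best-seen parameters every
    1,000 steps.  `perturbation_scale` is the log-scale width of the
    multiplicative proposal factor exp(sigma*Z).  Cooling is adaptive:
    the temperature is multiplied by `cool_fast` at a restart when the
    uphill-acceptance rate since the previous restart exceeded
    `uphill_rate_threshold`, by `cool_slow` otherwise.
    """

    steps_cold_start: int = 50_000
    steps_warm_start: int = 10_000
    restart_interval: int = 1_000
    n_cold_chains: int = 4
    perturbation_scale: float = 0.2
    initial_acceptance: float = 0.3
    calibration_steps: int = 100
    cool_fast: float = 0.9
    cool_slow: float = 0.97
    uphill_rate_threshold: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.steps_cold_start < 0 or self.steps_warm_start < 0:
            raise ValueError("step counts must be non-negative")
        if self.restart_interval <= 0:
            raise ValueError("restart_interval must be positive")
        if not (0 < self.initial_acceptance < 1):
            raise ValueError("initial_acceptance must be in (0, 1)")
        if self.n_cold_chains < 1:
            raise ValueError("n_cold_chains must be >= 1")
        if self.perturbation_scale <= 0:
            raise ValueError("perturbation_scale must be positive")

    def scaled(self, factor: float) -> "AnnealConfig":
        """Step budgets divided by `factor` (fast mode); at least 1 each.

        The restart interval is left alone: it sets how far the
        multiplicative walk can roam between collapses onto the best-seen
        point, and shrinking it degrades basin-finding independently of
        the budget.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        return replace(
            self,
            steps_cold_start=max(1, int(self.steps_cold_start / factor)),
            steps_warm_start=max(1, int(self.steps_warm_start / factor)),
        )

    def with_seed(self, seed) -> "AnnealConfig":
        return replace(self, seed=None if seed is None else int(seed))


@dataclass(frozen=True)
class FitResult:
    """Optimized parameters for one exponent pair plus provenance."""

    params: BPParameters
    sse: float
    n_points: int
    polished: bool = False
    anneal_steps: int = 0
    seed: int | None = None
    converged: bool = True

    @property
    def pair(self) -> ExponentPair:
        return self.params.pair


def sse_of(params: BPParameters, data: GrowthDataset, *,
           rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> float:
    """Sum of squared errors of the curve against the data; +inf when the
    curve cannot be integrated (the annealer then always rejects it)."""
    return float(_core.sse_log_params(
        data.times, data.volumes, params.a - 1.0, params.b - 1.0,
        math.log(params.p), math.log(params.q), math.log(params.v0),
        rtol, atol))


def _default_start(pair: ExponentPair, data: GrowthDataset) -> BPParameters:
    # p = q = 1 and v(t1) = v1: the standard cold-start estimate
    return BPParameters(pair, 1.0, 1.0, float(data.volumes[0]))


def _resolve_seed(seed) -> int:
    if seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    return int(seed) & 0x7FFFFFFF


def anneal_fit(pair: ExponentPair, data: GrowthDataset,
               config: AnnealConfig | None = None,
               start: BPParameters | None = None, *,
               warm: bool = False) -> FitResult:
    """Simulated-annealing minimization of SSE over (p, q, v0).

    `warm=True` (or an explicit `start`) uses the warm-start step budget
    and a single chain; a cold start initializes at p = q = 1, v0 = first
    observed volume and runs `n_cold_chains` independent chains with the
    full budget each, keeping the best.  The cold landscape has a strong
    spurious basin — a near-instant jump to the asymptote — that a single
    chain fails to leave on a sizeable fraction of seeds, so the extra
    chains use progressively wider proposal scales (which diffuse farther
    per restart interval).  Given the same data, pair, config and seed
    the result is reproducible bit-for-bit.
    """
    config = config or AnnealConfig()
    cold = start is None
    if cold:
        start = _default_start(pair, data)
        steps = config.steps_cold_start
        n_chains = config.n_cold_chains
    else:
        if start.pair != pair:
            start = BPParameters(pair, start.p, start.q, start.v0)
        steps = config.steps_warm_start if warm else config.steps_cold_start
        n_chains = 1 if warm else config.n_cold_chains
    seed = _resolve_seed(config.seed)
    if steps == 0:
        return FitResult(start, sse_of(start, data), len(data),
                         anneal_steps=0, seed=seed)
    # the raw seed is always chain 0, so adding chains can only improve
    chain_seeds = [seed] + [
        int(s) for s in np.random.SeedSequence(seed).generate_state(
            n_chains) % np.uint32(0x7FFFFFFF)][:n_chains - 1]
    best_out = None
    for k, cseed in enumerate(chain_seeds):
        sigma = config.perturbation_scale
        if n_chains > 1:
            sigma *= _CHAIN_SIGMA_FACTORS[k % len(_CHAIN_SIGMA_FACTORS)]
        lp, lq, lu0, best, accepted = _core.anneal_core(
            data.times, data.volumes, pair.a - 1.0, pair.b - 1.0,
            math.log(start.p), math.log(start.q), math.log(start.v0),
            steps, config.restart_interval, sigma,
            config.initial_acceptance, config.calibration_steps,
            config.cool_fast, config.cool_slow, config.uphill_rate_threshold,
            cseed, DEFAULT_RTOL, DEFAULT_ATOL)
        if best_out is None or best < best_out[3]:
            best_out = (lp, lq, lu0, best)
    lp, lq, lu0, best = best_out
    params = BPParameters(pair, math.exp(lp), math.exp(lq), math.exp(lu0))
    return FitResult(params, float(best), len(data),
                     anneal_steps=steps * len(chain_seeds),
                     seed=seed, converged=bool(np.isfinite(best)))


def polish_fit(pair: ExponentPair, data: GrowthDataset,
               start: BPParameters) -> FitResult:
    """Deterministic local least-squares refinement in log-parameter space.

    Works on x = (ln p, ln q, ln v0) so positivity is implicit and the
    tiny-q regimes stay conditioned; the loss is the same SSE.  If the
    local optimizer fails to improve, the start is returned unchanged
    with ``polished=False``.
    """
    t, v = data.times, data.volumes
    am1, bm1 = pair.a - 1.0, pair.b - 1.0

    def resid(x):
        u = _core.integrate_log(t, x[2], am1, bm1,
                                math.exp(x[0]), math.exp(x[1]),
                                DEFAULT_RTOL, DEFAULT_ATOL)
        r = v - np.exp(u)
        r[~np.isfinite(r)] = _BIG_RESIDUAL
        return r

    x0 = np.array([math.log(start.p), math.log(start.q), math.log(start.v0)])
    sse0 = sse_of(start, data)
    try:
        sol = least_squares(resid, x0, method="trf", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=400)
        sse1 = float(np.sum(sol.fun ** 2))
    except Exception:
        sse1 = np.inf
    if not np.isfinite(sse1) or sse1 > sse0:
        return FitResult(start, sse0, len(data), polished=False)
    params = BPParameters(pair, math.exp(sol.x[0]), math.exp(sol.x[1]),
                          math.exp(sol.x[2]))
    return FitResult(params, sse1, len(data), polished=True)


def fit_pair(pair: ExponentPair, data: GrowthDataset,
             config: AnnealConfig | None = None,
             start: BPParameters | None = None, *,
             warm: bool = False, polish: bool = True) -> FitResult:
    """Anneal then polish; returns the better of the two stages by SSE."""
    annealed = anneal_fit(pair, data, config, start, warm=warm)
    if not polish:
        return annealed
    polished = polish_fit(pair, data, annealed.params)
    if polished.sse <= annealed.sse:
        return replace(polished, anneal_steps=annealed.anneal_steps,
                       seed=annealed.seed, converged=annealed.converged)
    return annealed


def ladder_fit(pair: ExponentPair, data: GrowthDataset,
               config: AnnealConfig | None = None, *,
               rung: float = 0.5, polish: bool = True) -> FitResult:
    """Fit a large-gap exponent pair by warm-starting up a ladder in b.

    Pairs with b far above a need astronomically small q (q ~ 1e-29 at
    b ~ 9) that a cold annealing chain cannot reach directly; the grid
    protocol reaches them by warm-starting each pair from its left
    b-neighbor.  This helper reproduces that path for a single target
    pair: a cold fit near the diagonal, then warm fits at b increasing in
    steps of `rung` until the target exponent pair, followed by the
    usual polish.
    """
    config = config or AnnealConfig()
    n = max(1, int(math.ceil((pair.b - pair.a - 0.01) / rung)))
    bs = np.linspace(min(pair.a + 0.01, pair.b), pair.b, n + 1)
    prev = None
    fr = None
    for i, b in enumerate(bs):
        rung_pair = ExponentPair(pair.a, float(b))
        cfg = config if config.seed is None else config.with_seed(
            config.seed + i)
        fr = fit_pair(rung_pair, data, cfg, start=prev,
                      warm=prev is not None, polish=polish)
        prev = fr.params
    return fr
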