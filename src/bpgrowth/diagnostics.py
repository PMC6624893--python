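"""Fit diagnostics: residual distribution tests, spline-based numeric
differentiation of the data, growth-rate envelopes over near-optimal
models, and single-observation prediction bands.

Least squares implicitly assumes Gaussian residuals; the residual report
checks that assumption with a sign test for median zero and with
composite-normality Anderson-Darling and Cramer-von Mises tests (mean
and SD estimated from the residuals, which is the relevant variant for
fitted residuals).  The cubic spline provides a model-free estimate of
the relative growth rate v'/v for comparison with the fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .dataset import GrowthDataset
from .fitting import FitResult
from .landscape import SSELandscape
from .ode import relative_growth_rate, solve_curve

__all__ = ["ResidualReport", "residual_report", "spline_interpolate",
           "spline_rgr", "rgr_envelope", "prediction_band"]

_N_FREE_PARAMS = 3  # p, q, v0 optimized at fixed exponents


@dataclass(frozen=True)
class ResidualReport:
    """Residuals of one fit with scale and normality diagnostics."""

    residuals: np.ndarray
    sd: float
    sign_test_p: float
    anderson_darling_p: float
    cramer_von_mises_p: float
    notes: tuple[str, ...] = ()


def residual_report(fit: FitResult, data: GrowthDataset, *,
                    cvm_mc_samples: int = 2000, seed: int = 0
                    ) -> ResidualReport:
    """Residuals v_i - v(t_i), their SD (denominator n-1), and tests.

    The sign test is the exact two-sided binomial test for median zero
    (zeros dropped).  Anderson-Darling uses the normality variant with
    estimated parameters; the Cramer-von Mises p-value for the composite
    hypothesis is obtained by parametric-bootstrap Monte Carlo (seeded,
    `cvm_mc_samples` replicates).  With fewer than 3 residuals the tests
    are skipped (NaN p-values) with a notice.
    """
    pred = solve_curve(fit.params, data.times)
    resid = data.volumes - pred
    sd = float(np.std(resid, ddof=1))
    notes: list[str] = []
    if len(resid) < 3:
        return ResidualReport(resid, sd, np.nan, np.nan, np.nan,
                              ("too few residuals; tests skipped",))

    nonzero = resid[resid != 0]
    if nonzero.size == 0:
        sign_p = 1.0
        notes.append("all residuals zero; sign test degenerate")
    else:
        k = int(np.sum(nonzero > 0))
        sign_p = float(stats.binomtest(k, nonzero.size, 0.5).pvalue)

    if np.allclose(resid, resid[0]):
        ad_p = cvm_p = np.nan
        notes.append("constant residuals; normality tests skipped")
    else:
        from statsmodels.stats.diagnostic import normal_ad
        _, ad_p = normal_ad(resid)
        ad_p = float(ad_p)
        cvm_p = _cvm_composite_normal_p(resid, cvm_mc_samples, seed)
    return ResidualReport(resid, sd, sign_p, ad_p, cvm_p, tuple(notes))


def _cvm_composite_normal_p(x: np.ndarray, n_mc: int, seed) -> float:
    """Cramer-von Mises statistic against N(mean, sd) with estimated
    parameters; the null distribution is simulated (Lilliefors-style)."""
    def cvm_stat(sample):
        mu, sg = sample.mean(), sample.std(ddof=1)
        z = np.sort(stats.norm.cdf(sample, mu, sg))
        n = sample.size
        i = np.arange(1, n + 1)
        return 1.0 / (12 * n) + np.sum((z - (2 * i - 1) / (2 * n)) ** 2)

    obs = cvm_stat(x)
    rng = np.random.default_rng(seed)
    null = np.array([cvm_stat(rng.standard_normal(x.size))
                     for _ in range(n_mc)])
    return float((1 + np.sum(null >= obs)) / (1 + n_mc))


def spline_interpolate(data: GrowthDataset, *, bc_type: str = "natural"
                       ) -> CubicSpline:
    """Cubic spline through all observations (natural boundary by default,
    'not-a-knot' available); exact at the knots."""
    return CubicSpline(data.times, data.volumes, bc_type=bc_type)


def spline_rgr(data: GrowthDataset, times, *, bc_type: str = "natural"
               ) -> np.ndarray:
    """Model-free relative growth rate s'(t)/s(t) from the data spline.

    Times where the spline dips non-positive (possible between noisy
    knots) yield NaN — flagged gaps, not numbers.
    """
    s = spline_interpolate(data, bc_type=bc_type)
    t = np.asarray(times, dtype=float)
    val = s(t)
    out = np.full(t.shape, np.nan)
    ok = val > 0
    out[ok] = s(t[ok], 1) / val[ok]
    return out


def rgr_envelope(land: SSELandscape, threshold: float, times
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (min, max) of v'/v across all near-optimal model curves.

    The envelope always contains the best-fit curve's rate, and shrinks
    monotonically as the threshold shrinks (the model set is nested).
    """
    t = np.asarray(times, dtype=float)
    pairs = land.near_optimal(threshold)
    lo = np.full(t.shape, np.inf)
    hi = np.full(t.shape, -np.inf)
    for pr in pairs:
        fr = land.entries[pr]
        try:
            r = relative_growth_rate(fr.params, t)
        except Exception:
            continue
        lo = np.minimum(lo, r)
        hi = np.maximum(hi, r)
    return lo, hi


def _log_param_jacobian(fit: FitResult, times, rel_step: float = 1e-5
                        ) -> np.ndarray:
    """Finite-difference Jacobian of v(t) w.r.t. (ln p, ln q, ln v0)."""
    import math

    from .ode import BPParameters

    pm = fit.params
    x0 = np.array([math.log(pm.p), math.log(pm.q), math.log(pm.v0)])
    t = np.asarray(times, dtype=float)
    J = np.empty((t.size, 3))
    for j in range(3):
        for sgn, col in ((1.0, 0), (-1.0, 1)):
            x = x0.copy()
            x[j] += sgn * rel_step
            p = BPParameters(pm.pair, math.exp(x[0]), math.exp(x[1]),
                             math.exp(x[2]))
            v = solve_curve(p, t)
            if col == 0:
                vp = v
            else:
                vm = v
        J[:, j] = (vp - vm) / (2 * rel_step)
    return J


def prediction_band(fit: FitResult, data: GrowthDataset,
                    confidence: float = 0.95, times=None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """t-based single-observation prediction band around the fitted curve.

    Returns (curve, lower, upper) at `times` (default: the observation
    times).  The band is curve +/- t_{1-(1-c)/2, n-k} * s * sqrt(1 + h),
    with s^2 = SSE/(n-k), k = 3 fitted parameters, and leverage h from
    the finite-difference Jacobian of the curve in log-parameter space.
    A numerically singular Jacobian drops the leverage term (h = 0), so
    the band degrades gracefully to the residual-only band.
    """
    t = data.times if times is None else np.asarray(times, dtype=float)
    n = len(data)
    dof = n - _N_FREE_PARAMS
    if dof <= 0:
        raise ValueError("need more observations than parameters")
    curve = solve_curve(fit.params, t)
    s2 = fit.sse / dof
    Jobs = _log_param_jacobian(fit, data.times)
    Jt = _log_param_jacobian(fit, t) if times is not None else Jobs
    JtJ = Jobs.T @ Jobs
    try:
        JtJ_inv = np.linalg.inv(JtJ)
        h = np.einsum("ij,jk,ik->i", Jt, JtJ_inv, Jt)
        h = np.clip(h, 0.0, None)
    except np.linalg.LinAlgError:
        h = np.zeros(t.size)
    tq = stats.t.ppf(1 - (1 - confidence) / 2, dof)
    half = tq * np.sqrt(s2 * (1.0 + h))
    return curve, curve - half, curve + half
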