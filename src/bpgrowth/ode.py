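"""The Bertalanffy-Putter growth equation and its derived quantities.

The model family is the first-order ODE

    dv/dt = p * v**a - q * v**b,    v(t1) = v0 > 0,

for tumor volume v (mm^3) over time t (days).  Each exponent pair
(a, b) with 0 <= a < b fixes one three-parameter model (p, q, v0); the
classical named growth models are particular pairs — exponential (0, 1),
von Bertalanffy (2/3, 1), Verhulst/logistic (1, 2) — and the Gompertz
model is the diagonal limit a = b, which needs a different equation and
is deliberately outside this family.

For p, q, v0 > 0 trajectories are bounded and sigmoid, with carrying
capacity (p/q)**(1/(b-a)) and maximal growth rate at volume
(a*p/(b*q))**(1/(b-a)).

Numerical solution is done in log volume (see `bpgrowth._core`), which
preserves positivity and keeps the b-exponent term conditioned even for
the extreme fitted regimes (b ~ 10, q ~ 1e-34).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import integrate_log

__all__ = [
    "ExponentPair",
    "BPParameters",
    "CurveSolutionError",
    "bp_rhs",
    "solve_curve",
    "asymptotic_volume",
    "inflection_volume",
    "relative_growth_rate",
    "logistic_curve",
    "bounded_exponential_curve",
    "exponential_curve",
]

#: smallest admissible b - a; the fitting grid (spacing 0.01) never gets close
MIN_EXPONENT_GAP = 1e-6

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class CurveSolutionError(RuntimeError):
    """The growth-curve integration failed (blow-up or non-finite state)."""


@dataclass(frozen=True, order=True)
class ExponentPair:
    """Exponent pair (a, b) identifying one model of the family.

    Ordering is lexicographic (a, then b), which is also the tie-break
    order used when two fitted pairs reach the same SSE.
    """

    a: float
    b: float

    def __post_init__(self):
        if not (0 <= self.a):
            raise ValueError(f"exponent a must be >= 0, got {self.a}")
        if not (self.b - self.a >= MIN_EXPONENT_GAP):
            raise ValueError(
                f"need a < b with b - a >= {MIN_EXPONENT_GAP:g} "
                f"(the Gompertz diagonal a = b is excluded); "
                f"got a={self.a}, b={self.b}")

    def on_grid(self, spacing: float = 0.01, tol: float = 1e-9) -> bool:
        """Whether both exponents are integer multiples of `spacing`."""
        ra = self.a / spacing
        rb = self.b / spacing
        return (abs(ra - round(ra)) < tol) and (abs(rb - round(rb)) < tol)


@dataclass(frozen=True)
class BPParameters:
    """Full parameter set (a, b, p, q, v0) of one growth curve.

    p and q carry units mm^3^(1-a)/day and mm^3^(1-b)/day; q values as
    small as 1e-34 occur for large b, so p and q must be kept at full
    double precision when serialized.
    """

    pair: ExponentPair
    p: float
    q: float
    v0: float

    def __post_init__(self):
        if not (self.p > 0 and self.q > 0 and self.v0 > 0):
            raise ValueError(
                f"p, q, v0 must all be positive, got "
                f"p={self.p}, q={self.q}, v0={self.v0}")

    @property
    def a(self) -> float:
        return self.pair.a

    @property
    def b(self) -> float:
        return self.pair.b


def bp_rhs(v, params: BPParameters):
    """Growth rate dv/dt = p*v^a - q*v^b at volume(s) ``v`` (mm^3/day)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    out = params.p * v ** params.a - params.q * v ** params.b
    return float(out) if out.ndim == 0 else out


def solve_curve(params: BPParameters, times, *, rtol: float = DEFAULT_RTOL,
                atol: float = DEFAULT_ATOL, method: str = "rk45") -> np.ndarray:
    """Volumes v(t) of the growth curve at the requested times.

    The curve is anchored at the first requested time: v(times[0]) = v0.
    ``method`` selects the integrator: ``"rk45"`` (compiled adaptive
    Dormand-Prince in log volume, the default used throughout fitting) or
    ``"lsoda"`` (scipy's stiff-switching integrator on the same log-space
    equation, kept as an independent cross-check).

    Raises
    ------
    CurveSolutionError
        if the trajectory blows up or the integrator fails; never returns
        silent garbage.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    am1 = params.a - 1.0
    bm1 = params.b - 1.0
    if method == "rk45":
        u = integrate_log(t, np.log(params.v0), am1, bm1,
                          params.p, params.q, rtol, atol)
        if not np.all(np.isfinite(u)):
            raise CurveSolutionError(
                f"growth-curve integration blew up for {params}")
        return np.exp(u)
    elif method == "lsoda":
        from scipy.integrate import odeint

        def rhs(u, _t):
            x = min(am1 * u[0], 700.0)
            y = min(bm1 * u[0], 700.0)
            return params.p * np.exp(x) - params.q * np.exp(y)

        u, info = odeint(rhs, np.log(params.v0), t, rtol=rtol, atol=atol,
                         full_output=True)
        if info["message"] != "Integration successful." or \
                not np.all(np.isfinite(u)):
            raise CurveSolutionError(
                f"LSODA integration failed for {params}: {info['message']}")
        return np.exp(u[:, 0])
    raise ValueError(f"unknown method {method!r}")


def asymptotic_volume(params: BPParameters) -> float:
    """Carrying capacity (p/q)**(1/(b-a)), the limit of v(t) as t -> inf.

    This is the positive equilibrium of the growth equation; every
    trajectory with v0 > 0 converges to it monotonically.
    """
    return float(np.exp((np.log(params.p) - np.log(params.q))
                        / (params.b - params.a)))


def inflection_volume(params: BPParameters) -> float:
    """Volume (a*p/(b*q))**(1/(b-a)) at which dv/dt is maximal.

    This is where the curve's second derivative changes sign.  Requires
    a > 0; for a = 0 the growth rate is monotone decreasing in v and the
    sigmoid has no interior inflection.
    """
    if params.a <= 0:
        raise ValueError("inflection volume requires a > 0")
    return float(np.exp(
        (np.log(params.a) + np.log(params.p)
         - np.log(params.b) - np.log(params.q)) / (params.b - params.a)))


def relative_growth_rate(params: BPParameters, times, **solve_kw) -> np.ndarray:
    """Per-day relative rate v'/v = p*v^(a-1) - q*v^(b-1) along the curve."""
    v = solve_curve(params, times, **solve_kw)
    return params.p * v ** (params.a - 1.0) - params.q * v ** (params.b - 1.0)


# ---------------------------------------------------------------------------
# Closed forms for special exponent pairs.  These are kept analytic and are
# used as independent oracles for the numeric integrator; the exponential
# form also covers the q < 0 (unbounded growth) convention that the
# positive-parameter fitting path never touches.

def logistic_curve(times, p: float, q: float, v0: float) -> np.ndarray:
    """Verhulst solution for the pair (1, 2): K v0 e^{pt} / (K + v0(e^{pt}-1))."""
    t = np.asarray(times, dtype=float)
    K = p / q
    e = np.exp(p * (t - t[0]))
    return K * v0 * e / (K + v0 * (e - 1.0))


def bounded_exponential_curve(times, p: float, q: float, v0: float) -> np.ndarray:
    """Solution (p/q)(1 - d e^{-qt}) for the pair (0, 1), d fixed by v0."""
    t = np.asarray(times, dtype=float)
    K = p / q
    d = 1.0 - v0 / K
    return K * (1.0 - d * np.exp(-q * (t - t[0])))


def exponential_curve(times, q: float, v0: float) -> np.ndarray:
    """Pure exponential v0 e^{-qt} (the p = 0 case; q < 0 means growth)."""
    t = np.asarray(times, dtype=float)
    return v0 * np.exp(-q * (t - t[0]))
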