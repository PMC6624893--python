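"""Numba-compiled numerical kernels.

Everything here works in log space: the growth curve is integrated as
d(ln v)/dt = p*v^(a-1) - q*v^(b-1) and the optimizer walks in
(ln p, ln q, ln v0).  Exponent pairs with large b force q down to ~1e-34,
so raw-scale arithmetic would overflow or lose the parameters entirely;
log space keeps every quantity O(1)-conditioned.

These kernels are private.  `bpgrowth.ode.solve_curve` exposes the
integrator with validation and a scipy (LSODA) cross-check path;
`bpgrowth.fitting` wraps the annealer.
"""

import numpy as np
from numba import njit

# |ln v| beyond this is treated as a blown-up trajectory: volumes outside
# [e^-200, e^200] mm^3 are far past any biologically meaningful range and
# such candidates can only ever be rejected by the fit.
_LOG_LIMIT = 200.0
_EXP_CLIP = 700.0  # largest argument fed to exp(); past this exp overflows
_MAX_STEPS = 5000  # per solve; legitimate curves of this family need ~10^2


@njit(cache=True)
def _rhs_log(u, am1, bm1, p, q):
    """d(ln v)/dt at u = ln v for dv/dt = p v^a - q v^b."""
    x = am1 * u
    y = bm1 * u
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    if y > _EXP_CLIP:
        y = _EXP_CLIP
    return p * np.exp(x) - q * np.exp(y)


@njit(cache=True)
def integrate_log(t_eval, u0, am1, bm1, p, q, rtol, atol):
    """Adaptive Dormand-Prince 5(4) integration of ln v(t).

    Returns ln v at each requested time; NaN from the first time at which
    the trajectory left [-_LOG_LIMIT, _LOG_LIMIT], went non-finite, or
    exhausted the step budget (a blow-up / stiffness sentinel: the caller
    scores such curves +inf).  t_eval must be sorted ascending and the
    state is anchored at t_eval[0].
    """
    n = t_eval.shape[0]
    out = np.empty(n)
    t = t_eval[0]
    u = u0
    out[0] = u
    h = 1.0
    hmax = t_eval[n - 1] - t_eval[0]
    if hmax <= 0.0:
        hmax = 1.0
    # The equation is autonomous and scalar with a single, globally
    # attracting equilibrium u* = (ln p - ln q)/(b - a) (for p, q > 0 and
    # a < b), approached monotonically.  Once the state is within the
    # local error tolerance of u* the remaining outputs equal u* to that
    # same tolerance — filling them analytically avoids the explicit-RK
    # stability crawl at stiff equilibria.
    ustar = (np.log(p) - np.log(q)) / (bm1 - am1)
    nsteps = 0
    for i in range(1, n):
        tend = t_eval[i]
        if abs(u - ustar) < 2.0 * (atol + rtol * abs(ustar)):
            u = ustar
            out[i] = u
            t = tend
            continue
        while t < tend:
            if abs(u - ustar) < 2.0 * (atol + rtol * abs(ustar)):
                u = ustar
                t = tend
                break
            nsteps += 1
            if nsteps > _MAX_STEPS:
                for j in range(i, n):
                    out[j] = np.nan
                return out
            step = h
            if step > tend - t:
                step = tend - t
            k1 = _rhs_log(u, am1, bm1, p, q)
            k2 = _rhs_log(u + step * 0.2 * k1, am1, bm1, p, q)
            k3 = _rhs_log(u + step * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2),
                          am1, bm1, p, q)
            k4 = _rhs_log(u + step * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2
                                      + 32.0 / 9.0 * k3), am1, bm1, p, q)
            k5 = _rhs_log(u + step * (19372.0 / 6561.0 * k1
                                      - 25360.0 / 2187.0 * k2
                                      + 64448.0 / 6561.0 * k3
                                      - 212.0 / 729.0 * k4), am1, bm1, p, q)
            k6 = _rhs_log(u + step * (9017.0 / 3168.0 * k1 - 355.0 / 33.0 * k2
                                      + 46732.0 / 5247.0 * k3
                                      + 49.0 / 176.0 * k4
                                      - 5103.0 / 18656.0 * k5),
                          am1, bm1, p, q)
            unew = u + step * (35.0 / 384.0 * k1 + 500.0 / 1113.0 * k3
                               + 125.0 / 192.0 * k4 - 2187.0 / 6784.0 * k5
                               + 11.0 / 84.0 * k6)
            k7 = _rhs_log(unew, am1, bm1, p, q)
            uerr = step * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1
                           + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3
                           + (125.0 / 192.0 - 393.0 / 640.0) * k4
                           + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5
                           + (11.0 / 84.0 - 187.0 / 2100.0) * k6
                           - 1.0 / 40.0 * k7)
            au = abs(u)
            aun = abs(unew)
            sc = atol + rtol * (au if au > aun else aun)
            err = abs(uerr) / sc
            if err <= 1.0 or step <= 1e-12:
                t = t + step
                u = unew
                if not np.isfinite(u) or abs(u) > _LOG_LIMIT:
                    for j in range(i, n):
                        out[j] = np.nan
                    return out
            if err > 0.0:
                fac = 0.9 * err ** (-0.2)
                if fac < 0.2:
                    fac = 0.2
                elif fac > 5.0:
                    fac = 5.0
                h = step * fac
            else:
                h = step * 5.0
            if h > hmax:
                h = hmax
            if h < 1e-12:
                h = 1e-12
        out[i] = u
    return out


@njit(cache=True)
def sse_log_params(t, v, am1, bm1, lp, lq, lu0, rtol, atol):
    """SSE of the curve defined by log parameters against observations.

    Returns +inf for trajectories the integrator flags as blown up, so the
    annealer can treat infeasible parameter triples as always-rejected.
    """
    u = integrate_log(t, lu0, am1, bm1, np.exp(lp), np.exp(lq), rtol, atol)
    sse = 0.0
    for i in range(t.shape[0]):
        if not np.isfinite(u[i]):
            return np.inf
        r = v[i] - np.exp(u[i])
        sse += r * r
    return sse


@njit(cache=True)
def anneal_core(t, v, am1, bm1, lp0, lq0, lu00, steps, restart_interval,
                sigma, initial_acceptance, calib_steps, cool_fast, cool_slow,
                uphill_rate_threshold, seed, rtol, atol):
    """Multiplicative simulated annealing over (p, q, v0) at fixed exponents.

    Proposals multiply each parameter by exp(sigma * Z), Z ~ N(0,1) — a
    positive factor close to 1, which keeps parameters positive and makes
    the step size scale free.  Uphill moves are accepted Metropolis-style
    with probability exp(-dSSE/T).

    The temperature is tied to the optimization state: T = c * best_sse,
    so it tracks the SSE scale downward as the fit improves (the SSE
    drops by many orders of magnitude from the naive start p = q = 1).
    The constant c is calibrated during the first `calib_steps` proposals
    — uphill moves are then accepted with probability
    `initial_acceptance`, and the observed mean uphill dSSE fixes c so
    that such a move would be accepted with that probability — and is
    cooled at every restart: by `cool_fast` when the uphill-acceptance
    rate since the previous restart exceeded `uphill_rate_threshold`,
    else by the gentler `cool_slow`.  Every `restart_interval` steps the
    chain restarts from the best-seen parameters.

    Returns (best_lp, best_lq, best_lu0, best_sse, accepted_count).
    """
    np.random.seed(seed)
    lp = lp0
    lq = lq0
    lu0 = lu00
    cur = sse_log_params(t, v, am1, bm1, lp, lq, lu0, rtol, atol)
    best_lp, best_lq, best_lu0 = lp, lq, lu0
    best = cur

    c = -1.0  # temperature coefficient, calibrated after calib_steps
    calib_sum = 0.0
    calib_n = 0
    uphill_prop = 0
    uphill_acc = 0
    accepted = 0

    for step in range(1, steps + 1):
        zp = np.random.normal()
        zq = np.random.normal()
        zu = np.random.normal()
        nlp = lp + sigma * zp
        nlq = lq + sigma * zq
        nlu0 = lu0 + sigma * zu
        s = sse_log_params(t, v, am1, bm1, nlp, nlq, nlu0, rtol, atol)
        take = False
        if s <= cur:
            take = True
        elif np.isfinite(s) and np.isfinite(cur):
            d = s - cur
            uphill_prop += 1
            if c < 0.0:
                calib_sum += d
                calib_n += 1
                if np.random.random() < initial_acceptance:
                    take = True
            else:
                T = c * best if best > 0.0 else c
                arg = -d / T if T > 0.0 else -np.inf
                if arg > -_EXP_CLIP and np.random.random() < np.exp(arg):
                    take = True
            if take:
                uphill_acc += 1
        if take:
            lp, lq, lu0, cur = nlp, nlq, nlu0, s
            accepted += 1
            # ties update the best-seen POINT as well: on flat plateaus
            # this lets the restart mechanism follow the chain's drift
            # instead of teleporting it back across the plateau
            if cur <= best:
                best = cur
                best_lp, best_lq, best_lu0 = lp, lq, lu0
        if c < 0.0 and step >= calib_steps and calib_n > 0 and best > 0.0:
            # c such that the mean uphill move observed so far would be
            # accepted with the configured initial probability
            c = (calib_sum / calib_n) / (-np.log(initial_acceptance)) / best
        if restart_interval > 0 and step % restart_interval == 0:
            lp, lq, lu0, cur = best_lp, best_lq, best_lu0, best
            if c > 0.0:
                if uphill_prop > 0 and \
                        uphill_acc > uphill_rate_threshold * uphill_prop:
                    c *= cool_fast
                else:
                    c *= cool_slow
            uphill_prop = 0
            uphill_acc = 0
    return best_lp, best_lq, best_lu0, best, accepted
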