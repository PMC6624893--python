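"""Growth-equation layer: right-hand side, curve solutions against
closed-form oracles, derived volumes, and the qualitative invariants
(equilibrium, boundedness, monotonicity)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpgrowth import (BPParameters, CurveSolutionError, ExponentPair,
                      asymptotic_volume, bp_rhs, inflection_volume,
                      relative_growth_rate, solve_curve)
from bpgrowth.ode import (bounded_exponential_curve, exponential_curve,
                          logistic_curve)


class TestExponentPair:
    def test_diagonal_and_disorder_rejected(self):
        with pytest.raises(ValueError):
            ExponentPair(1.0, 1.0)
        with pytest.raises(ValueError):
            ExponentPair(2.0, 1.0)
        with pytest.raises(ValueError):
            ExponentPair(-0.1, 1.0)

    def test_grid_membership(self):
        assert ExponentPair(1.62, 2.44).on_grid(0.01)
        assert not ExponentPair(1.625, 2.44).on_grid(0.01)

    def test_ordering_is_lexicographic(self):
        assert ExponentPair(1.0, 2.0) < ExponentPair(1.0, 2.5)
        assert ExponentPair(1.0, 3.0) < ExponentPair(1.1, 1.2)


class TestBPParameters:
    @pytest.mark.parametrize("p,q,v0", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_positivity_enforced(self, p, q, v0):
        with pytest.raises(ValueError):
            BPParameters(ExponentPair(1, 2), p, q, v0)


class TestRHS:
    def test_unit_volume_collapses_exponents(self):
        # v = 1 makes v^a = v^b = 1 for any pair
        pm = BPParameters(ExponentPair(0.3, 1.7), 0.5, 0.2, 1.0)
        assert bp_rhs(1.0, pm) == pytest.approx(0.3, abs=1e-15)

    def test_equilibrium_is_root(self):
        pm = BPParameters(ExponentPair(1.0, 2.0), 0.1, 2e-5, 100.0)
        K = asymptotic_volume(pm)
        assert bp_rhs(K, pm) == pytest.approx(0.0, abs=1e-12 * pm.p * K)

    def test_best_fit_rate_at_initial_volume(self):
        # direct arithmetic: p v^a - q v^b at the full-data optimum
        pm = BPParameters(ExponentPair(1.62, 2.44), 5.02e-4, 5.55e-7, 318.5)
        v = 318.5
        expected = 5.02e-4 * v**1.62 - 5.55e-7 * v**2.44
        assert bp_rhs(v, pm) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(4.9872, rel=1e-3)  # frozen value

    def test_nonpositive_volume_rejected(self):
        pm = BPParameters(ExponentPair(1, 2), 1, 1, 1)
        with pytest.raises(ValueError):
            bp_rhs(0.0, pm)
        with pytest.raises(ValueError):
            bp_rhs(np.array([1.0, -3.0]), pm)


class TestSolveCurve:
    def test_logistic_closed_form(self):
        # Verhulst pair (1, 2): known closed form, rel. tol 1e-6 on [0, 200]
        pm = BPParameters(ExponentPair(1.0, 2.0), 0.08, 2e-5, 250.0)
        t = np.linspace(0, 200, 101)
        num = solve_curve(pm, t)
        ana = logistic_curve(t, pm.p, pm.q, pm.v0)
        np.testing.assert_allclose(num, ana, rtol=1e-6)

    def test_bounded_exponential_closed_form(self):
        # pair (0, 1): v(t) = (p/q)(1 - d e^{-qt})
        pm = BPParameters(ExponentPair(0.0, 1.0), 60.0, 0.02, 225.0)
        t = np.linspace(0, 200, 101)
        num = solve_curve(pm, t)
        ana = bounded_exponential_curve(t, pm.p, pm.q, pm.v0)
        np.testing.assert_allclose(num, ana, rtol=1e-6)

    def test_equilibrium_start_stays_constant(self):
        pm0 = BPParameters(ExponentPair(1.0, 2.0), 0.1, 1e-4, 1.0)
        K = asymptotic_volume(pm0)
        pm = BPParameters(pm0.pair, pm0.p, pm0.q, K)
        v = solve_curve(pm, np.linspace(0, 150, 40))
        np.testing.assert_allclose(v, K, rtol=1e-8)

    def test_anchored_at_first_time(self):
        pm = BPParameters(ExponentPair(1.0, 2.0), 0.05, 1e-5, 300.0)
        t = np.array([10.0, 20.0, 50.0])
        v = solve_curve(pm, t)
        assert v[0] == pytest.approx(300.0)

    def test_integrator_cross_check(self):
        # compiled RK path vs scipy LSODA on an extreme-exponent curve
        pm = BPParameters(ExponentPair(1.34, 8.83), 2.27e-3, 2.28e-29, 323.5)
        t = np.linspace(0, 114, 30)
        np.testing.assert_allclose(solve_curve(pm, t, method="rk45"),
                                   solve_curve(pm, t, method="lsoda"),
                                   rtol=1e-6)

    def test_blowup_is_flagged_not_silent(self):
        # q >> p with tiny b - a: equilibrium at e^{-6900} mm^3, far below
        # any representable volume; must raise, not return garbage
        pm = BPParameters(ExponentPair(0.68, 0.69), 1e-3, 1.0, 100.0)
        with pytest.raises(CurveSolutionError):
            solve_curve(pm, np.linspace(0, 114, 14))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.0, 2.0), gap=st.floats(0.05, 2.0),
           logp=st.floats(-4, 1), logratio=st.floats(-8, 8),
           v0=st.floats(50, 2000))
    def test_bounded_and_monotone(self, a, gap, logp, logratio, v0):
        """Positive-parameter curves stay within (0, max(v0, K)] and are
        monotone toward the carrying capacity."""
        pair = ExponentPair(round(a, 2), round(a + gap, 2))
        K_target = np.exp(logratio)  # asymptote in units of v0
        p = 10.0 ** logp
        q = p / (K_target * v0) ** (pair.b - pair.a)
        pm = BPParameters(pair, p, q, v0)
        K = asymptotic_volume(pm)
        t = np.linspace(0, 200, 50)
        try:
            v = solve_curve(pm, t)
        except CurveSolutionError:
            # legitimate only for far-sub-representable equilibria
            assert np.log(K) < -150 or np.log(K) > 150
            return
        assert np.all(v > 0)
        assert np.all(v <= max(v0, K) * (1 + 1e-6))
        dv = np.diff(v)
        if v0 < K * (1 - 1e-9):
            assert np.all(dv >= -1e-9 * v[:-1])
        elif v0 > K * (1 + 1e-9):
            assert np.all(dv <= 1e-9 * v[:-1])


class TestDerivedVolumes:
    def test_asymptote_simple_ratio(self):
        pm = BPParameters(ExponentPair(1, 2), 0.3, 0.3, 5.0)
        assert asymptotic_volume(pm) == pytest.approx(1.0)

    def test_asymptote_tiny_gap_direct_arithmetic(self):
        # (p/q)^(1/0.01) from the 65-day optimum's parameters
        pm = BPParameters(ExponentPair(0.68, 0.69), 0.185, 8.66e-3, 266.2)
        expected = (0.185 / 8.66e-3) ** (1.0 / 0.01)
        assert asymptotic_volume(pm) == pytest.approx(expected, rel=1e-9)

    def test_asymptote_is_numeric_limit(self):
        pm = BPParameters(ExponentPair(1.0, 2.0), 0.1, 2.5e-5, 500.0)
        far = solve_curve(pm, np.array([0.0, 2000.0]))[-1]
        assert far == pytest.approx(asymptotic_volume(pm), rel=1e-6)

    def test_logistic_inflection_is_half_capacity(self):
        pm = BPParameters(ExponentPair(1.0, 2.0), 0.1, 2.5e-5, 500.0)
        assert inflection_volume(pm) == pytest.approx(
            asymptotic_volume(pm) / 2, rel=1e-12)

    def test_inflection_matches_dense_scan(self):
        # brute-force argmax of the growth rate over volume
        pm = BPParameters(ExponentPair(1.62, 2.44), 5.02e-4, 5.55e-7, 318.5)
        K = asymptotic_volume(pm)
        v = np.linspace(1e-3, K, 2_000_001)
        argmax = v[np.argmax(bp_rhs(v, pm))]
        assert inflection_volume(pm) == pytest.approx(argmax, rel=1e-4)

    def test_inflection_below_asymptote(self):
        for a, b in [(0.5, 1.0), (1.0, 2.0), (1.62, 2.44), (2.0, 2.1)]:
            pm = BPParameters(ExponentPair(a, b), 0.02, 3e-6, 100.0)
            assert inflection_volume(pm) < asymptotic_volume(pm)

    def test_inflection_requires_positive_a(self):
        pm = BPParameters(ExponentPair(0.0, 1.0), 1.0, 0.01, 100.0)
        with pytest.raises(ValueError):
            inflection_volume(pm)


class TestRelativeGrowthRate:
    def test_zero_at_asymptote(self):
        pm0 = BPParameters(ExponentPair(1.0, 2.0), 0.1, 1e-4, 1.0)
        K = asymptotic_volume(pm0)
        pm = BPParameters(pm0.pair, pm0.p, pm0.q, K)
        r = relative_growth_rate(pm, np.linspace(0, 100, 11))
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_pure_exponential_closed_form(self):
        # p = 0, q < 0 convention lives only in the analytic helper
        t = np.linspace(0, 50, 26)
        v = exponential_curve(t, -0.1, 10.0)
        np.testing.assert_allclose(np.diff(np.log(v)) / np.diff(t), 0.1,
                                   rtol=1e-12)

    def test_matches_log_derivative(self):
        pm = BPParameters(ExponentPair(1.62, 2.44), 5.02e-4, 5.55e-7, 318.5)
        t = np.linspace(0, 114, 400)
        r = relative_growth_rate(pm, t)
        v = solve_curve(pm, t)
        num = np.gradient(np.log(v), t)
        np.testing.assert_allclose(r[2:-2], num[2:-2], rtol=1e-3)
        mid = len(t) // 2
        assert r[mid] == pytest.approx(num[mid], rel=1e-4)
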