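"""Grid sweeps: geometry, warm starts, boundary extension, near-optimal
regions and serialization."""

import numpy as np
import pytest

from bpgrowth import (AnnealConfig, BPParameters, ExponentPair, FitResult,
                      GridSpec, SSELandscape, best_pair, extend_if_boundary,
                      fit_pair, generate_synthetic, near_optimal_region,
                      sweep)
from bpgrowth.landscape import _pair_seed, frayed_entries


def _manual_landscape(entries_spec, grid=None):
    """Build a landscape from {(a, b): sse} without running any fits."""
    entries = {}
    for (a, b), sse in entries_spec.items():
        pair = ExponentPair(a, b)
        pm = BPParameters(pair, 1.0, 1.0, 1.0)
        entries[pair] = FitResult(pm, sse, 0)
    return SSELandscape(entries, grid or GridSpec(spacing=0.1, a_max=1.0,
                                                  b_max=2.0))


class TestGridSpec:
    def test_pairs_respect_order_and_bounds(self):
        g = GridSpec(spacing=0.1, a_max=0.3, b_max=0.5)
        pairs = g.pairs()
        assert all(p.a < p.b for p in pairs)
        assert all(p.b <= 0.5 + 1e-12 for p in pairs)
        # a in {0, .1, .2, .3}; b from a+0.1 to 0.5
        assert len(pairs) == 5 + 4 + 3 + 2
        assert ExponentPair(0.2, 0.3) in pairs

    def test_contains(self):
        g = GridSpec(spacing=0.01)
        assert g.contains(ExponentPair(1.62, 2.44))
        assert not g.contains(ExponentPair(1.625, 2.44))
        assert not g.contains(ExponentPair(1.62, 5.0))

    def test_validation(self):
        with pytest.raises(ValueError):
            GridSpec(spacing=0.0)
        with pytest.raises(ValueError):
            GridSpec(a_max=-1.0)


class TestRegions:
    def test_threshold_zero_is_argmin(self):
        land = _manual_landscape({(0.1, 0.2): 5.0, (0.1, 0.3): 4.0,
                                  (0.2, 0.3): 6.0})
        assert near_optimal_region(land, 0.0) == {ExponentPair(0.1, 0.3)}

    def test_nesting(self):
        rng = np.random.default_rng(0)
        spec = {(round(a, 1), round(a + db, 1)): float(rng.uniform(1, 2))
                for a in np.arange(0, 1.0, 0.1)
                for db in np.arange(0.1, 0.6, 0.1)}
        land = _manual_landscape(spec)
        r1 = near_optimal_region(land, 0.01)
        r5 = near_optimal_region(land, 0.05)
        r10 = near_optimal_region(land, 0.10)
        assert r1 <= r5 <= r10
        assert best_pair(land)[0] in r1

    def test_negative_threshold_and_empty_landscape(self):
        land = _manual_landscape({(0.1, 0.2): 5.0})
        with pytest.raises(ValueError):
            near_optimal_region(land, -0.1)
        empty = SSELandscape({}, GridSpec())
        with pytest.raises(ValueError):
            best_pair(empty)

    def test_tie_break_lexicographic(self):
        land = _manual_landscape({(0.3, 0.4): 1.0, (0.1, 0.9): 1.0,
                                  (0.1, 0.5): 1.0})
        assert best_pair(land)[0] == ExponentPair(0.1, 0.5)


class TestSweep:
    def test_single_pair_grid_equals_fit_pair(self, paper):
        g = GridSpec(spacing=0.01, a_min=1.0, a_max=1.0, b_max=1.01)
        cfg = AnnealConfig(seed=5).scaled(10)
        land = sweep(g, paper, cfg)
        assert len(land) == 1
        pair = ExponentPair(1.0, 1.01)
        direct = fit_pair(pair, paper,
                          cfg.with_seed(_pair_seed(5, 1.0, 1.01)))
        assert land.entries[pair].sse == pytest.approx(direct.sse, rel=1e-12)
        assert land.entries[pair].params == direct.params

    def test_sweep_covers_grid_and_finds_min(self, truth_params):
        # noiseless data generated from (1.6, 2.4): the sweep over a tiny
        # grid around it must put the minimum at the generating cell
        pm = BPParameters(ExponentPair(1.6, 2.4), 5.02e-4, 5.55e-7, 318.5)
        t = np.linspace(0, 114, 14)
        d = generate_synthetic(pm, t, 0.0)
        g = GridSpec(spacing=0.1, a_min=1.4, a_max=1.8, b_max=2.6)
        land = sweep(g, d, AnnealConfig(seed=2).scaled(5))
        assert len(land) == len(g.pairs())
        bp_, fr = land.best()
        assert bp_ == ExponentPair(1.6, 2.4)
        assert fr.sse < 1.0

    def test_warm_start_dominance(self, paper):
        """Along a b-row, warm-started fits are at least as good as cold
        1,000-step fits at the same pair (median over seeds)."""
        g = GridSpec(spacing=0.1, a_min=1.0, a_max=1.0, b_max=1.6)
        pairs = g.pairs()
        warm_sse = {p: [] for p in pairs}
        cold_sse = {p: [] for p in pairs}
        for seed in (11, 12, 13):
            land = sweep(g, paper, AnnealConfig(seed=seed), polish=False,
                         retry_frayed=False)
            for p in pairs:
                warm_sse[p].append(land.entries[p].sse)
            for p in pairs:
                cfg = AnnealConfig(steps_cold_start=1000, seed=seed + 100)
                cold_sse[p].append(fit_pair(p, paper, cfg, polish=False).sse)
        for p in pairs:
            assert np.median(warm_sse[p]) <= np.median(cold_sse[p]) * 1.001


class TestExtension:
    def test_interior_minimum_unchanged(self):
        land2 = _manual_landscape({(0.0, 0.2): 5.0, (0.0, 0.3): 1.0,
                                   (0.0, 0.4): 5.0, (0.1, 0.3): 6.0},
                                  GridSpec(spacing=0.1, a_max=0.1, b_max=0.4))
        out = extend_if_boundary(land2, None, AnnealConfig(seed=1))
        assert out.entries == land2.entries
        assert out.optimality_secured

    def test_recovers_pair_outside_initial_region(self):
        truth = BPParameters(ExponentPair(1.0, 2.0), 0.08, 2e-5, 250.0)
        t = np.linspace(0, 114, 14)
        d = generate_synthetic(truth, t, 0.0)
        g = GridSpec(spacing=0.1, a_min=0.9, a_max=1.1, b_max=1.5)
        cfg = AnnealConfig(seed=4).scaled(5)
        land = sweep(g, d, cfg)
        out = extend_if_boundary(land, d, cfg, increment=0.5, b_cap=3.0)
        bp_, fr = out.best()
        assert out.grid.b_max > 1.5  # extension happened
        assert bp_ == ExponentPair(1.0, 2.0)

    def test_cap_flags_unsecured_optimality(self):
        land = _manual_landscape({(0.0, 0.1): 5.0, (0.0, 0.2): 1.0},
                                 GridSpec(spacing=0.1, a_max=0.0, b_max=0.2))
        with pytest.warns(UserWarning, match="not secured"):
            out = extend_if_boundary(land, None, AnnealConfig(seed=1),
                                     b_cap=0.2, a_cap=0.0)
        assert not out.optimality_secured


class TestFrayedCheck:
    def test_outlier_entry_detected(self):
        spec = {(round(a, 1), round(a + db, 1)): 1.0
                for a in np.arange(0, 1.0, 0.1)
                for db in np.arange(0.1, 0.6, 0.1)}
        spec[(0.5, 0.8)] = 10.0  # stuck fit: 10x its neighborhood
        land = _manual_landscape(spec)
        bad = frayed_entries(land)
        assert ExponentPair(0.5, 0.8) in bad
        assert len(bad) <= 3  # flags the outlier, not the smooth bulk


class TestSerialization:
    def test_csv_round_trip_is_lossless(self, tmp_path):
        entries = {}
        # include a Table-2-extreme q to exercise precision
        for (a, b, p, q, v0, sse) in [
            (1.62, 2.44, 5.0234567890123456e-4, 5.5512345678901234e-7,
             318.51234567890123, 1.2741234567890123e5),
            (1.34, 8.83, 2.27e-3, 2.2812345678901234e-29, 323.5, 6.12e4),
        ]:
            pair = ExponentPair(a, b)
            entries[pair] = FitResult(
                BPParameters(pair, p, q, v0), sse, 14)
        land = SSELandscape(entries, GridSpec())
        path = tmp_path / "land.csv"
        land.to_csv(path)
        back = SSELandscape.from_csv(path)
        for pair, fr in entries.items():
            bfr = back.entries[pair]
            assert bfr.params.p == fr.params.p
            assert bfr.params.q == fr.params.q
            assert bfr.params.v0 == fr.params.v0
            assert bfr.sse == fr.sse

    def test_region_frame_flags(self):
        land = _manual_landscape({(0.1, 0.2): 1.0, (0.1, 0.3): 1.04,
                                  (0.2, 0.3): 1.2})
        df = land.region_frame()
        flags = {(r.a, r.b): r.threshold_flag for r in
                 df.itertuples(index=False)}
        assert flags[(0.1, 0.2)] == 0.01
        assert flags[(0.1, 0.3)] == 0.05
        assert np.isnan(flags[(0.2, 0.3)])
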