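"""SSE landscapes over the exponent grid.

The model family is scanned on a grid a = m*s, b = a + n*s (spacing
s = 0.01 by default, integers m >= 0, n >= 1).  Fitting every grid pair
yields the landscape SSE_opt(a, b) = min_{p,q,v0} SSE, whose sub-level
sets — the near-optimal regions — measure how well the data identify a
growth model: a large region means many qualitatively different curves
fit almost equally well.

The sweep runs an outer loop over a and an inner loop over ascending b;
the first pair of each row (a, a + s) is fitted from a cold start with
the full annealing budget, and each subsequent pair warm-starts from its
left neighbor's optimum with the reduced budget.  If the best pair lands
on the grid's upper (max b) or right (max a) boundary the grid is
extended in that direction and re-swept until the optimum is interior or
a hard cap is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import GrowthDataset
from .fitting import AnnealConfig, FitResult, fit_pair
from .ode import BPParameters, ExponentPair

__all__ = ["GridSpec", "SSELandscape", "sweep", "extend_if_boundary",
           "near_optimal_region", "best_pair"]

#: default initial search rectangle; covers all the named models
#: (exponential (0,1), von Bertalanffy (2/3,1), Verhulst (1,2), the
#: generalized-Bertalanffy line b = 1 and the Richards line a = 1)
DEFAULT_A_MAX = 2.1
DEFAULT_B_MAX = 3.1


def _snap(x: float, spacing: float) -> float:
    return round(round(x / spacing) * spacing, 10)


@dataclass(frozen=True)
class GridSpec:
    """Exponent-pair grid geometry: 0 <= a <= a_max, a < b <= b_max."""

    spacing: float = 0.01
    a_max: float = DEFAULT_A_MAX
    b_max: float = DEFAULT_B_MAX
    a_min: float = 0.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.a_min < 0 or self.a_max < self.a_min or \
                self.b_max <= self.a_min:
            raise ValueError("invalid grid bounds")

    def a_values(self) -> np.ndarray:
        m0 = round(self.a_min / self.spacing)
        m1 = int(np.floor(self.a_max / self.spacing + 1e-9))
        return np.array([_snap(m * self.spacing, self.spacing)
                         for m in range(m0, m1 + 1)])

    def b_values(self, a: float) -> np.ndarray:
        n1 = int(np.floor((self.b_max - a) / self.spacing + 1e-9))
        return np.array([_snap(a + n * self.spacing, self.spacing)
                         for n in range(1, n1 + 1)])

    def pairs(self) -> list[ExponentPair]:
        return [ExponentPair(a, b)
                for a in self.a_values() for b in self.b_values(a)]

    def contains(self, pair: ExponentPair) -> bool:
        return (self.a_min - 1e-9 <= pair.a <= self.a_max + 1e-9
                and pair.b <= self.b_max + 1e-9
                and pair.on_grid(self.spacing))


@dataclass
class SSELandscape:
    """Mapping of fitted grid pairs to their optimization results."""

    entries: dict[ExponentPair, FitResult]
    grid: GridSpec
    data_label: str = ""
    optimality_secured: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def min_sse(self) -> float:
        return self.best()[1].sse

    def best(self) -> tuple[ExponentPair, FitResult]:
        if not self.entries:
            raise ValueError("empty landscape")
        # argmin by SSE; ties break to the lexicographically smaller pair
        return min(self.entries.items(), key=lambda kv: (kv[1].sse, kv[0]))

    def near_optimal(self, threshold: float) -> set[ExponentPair]:
        lo = self.min_sse
        return {pr for pr, fr in self.entries.items()
                if fr.sse <= (1.0 + threshold) * lo}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries.items(), key=lambda kv: kv[0])
        return pd.DataFrame(
            [(pr.a, pr.b, fr.params.v0, fr.params.p, fr.params.q, fr.sse)
             for pr, fr in rows],
            columns=["a", "b", "v0", "p", "q", "sse"])

    def to_csv(self, path) -> None:
        # %.17g keeps >= 15 significant digits so tiny q values survive
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, grid: GridSpec | None = None,
                 data_label: str = "") -> "SSELandscape":
        df = pd.read_csv(path, float_precision="round_trip")
        entries: dict[ExponentPair, FitResult] = {}
        n_points = 0
        for row in df.itertuples(index=False):
            pr = ExponentPair(float(row.a), float(row.b))
            params = BPParameters(pr, float(row.p), float(row.q),
                                  float(row.v0))
            entries[pr] = FitResult(params, float(row.sse), n_points)
        if grid is None:
            spacing = 0.01
            grid = GridSpec(spacing=spacing,
                            a_max=float(df["a"].max()),
                            b_max=float(df["b"].max()))
        return cls(entries, grid, data_label=data_label)

    def region_frame(self, thresholds=(0.01, 0.05, 0.10)) -> pd.DataFrame:
        """(a, b, threshold_flag) rows for plotting near-optimal maps;
        the flag is the smallest threshold at which the pair qualifies
        (NaN when it qualifies for none)."""
        lo = self.min_sse
        recs = []
        for pr, fr in sorted(self.entries.items(), key=lambda kv: kv[0]):
            flag = np.nan
            for th in sorted(thresholds):
                if fr.sse <= (1.0 + th) * lo:
                    flag = th
                    break
            recs.append((pr.a, pr.b, flag))
        return pd.DataFrame(recs, columns=["a", "b", "threshold_flag"])


def _pair_seed(base_seed, a: float, b: float, salt: int = 0):
    if base_seed is None:
        return None
    ss = np.random.SeedSequence([int(base_seed), salt,
                                 int(round(a * 1000)), int(round(b * 1000))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _fit_row(a: float, b_vals, data, config, start, polish):
    """Fit one constant-a row for ascending b, warm-starting along b."""
    out: dict[ExponentPair, FitResult] = {}
    prev = start  # None -> cold start at the row head
    for j, b in enumerate(b_vals):
        pair = ExponentPair(a, b)
        cfg = config.with_seed(_pair_seed(config.seed, a, b))
        fr = fit_pair(pair, data, cfg, start=prev, warm=prev is not None,
                      polish=polish)
        out[pair] = fr
        prev = fr.params
    return out


def sweep(grid: GridSpec, data: GrowthDataset,
          config: AnnealConfig | None = None, *, polish: bool = True,
          retry_frayed: bool = True) -> SSELandscape:
    """Fit every grid pair; returns the completed landscape.

    Individual pair failures are recorded as +inf entries and the sweep
    continues.  With ``retry_frayed``, entries whose SSE deviates by more
    than 50% from the median of their grid neighbors (the signature of an
    annealing chain stuck in the wrong basin, which warm starts then
    propagate along a row) are re-fitted — warm-started from the best
    neighboring optimum and, on the first pass, also cold with a 5x
    budget — for up to three passes.
    """
    config = config or AnnealConfig()
    entries: dict[ExponentPair, FitResult] = {}
    for a in grid.a_values():
        b_vals = grid.b_values(a)
        if b_vals.size == 0:
            continue
        entries.update(_fit_row(a, b_vals, data, config, None, polish))
    land = SSELandscape(entries, grid, data_label=data.label)
    if retry_frayed:
        _retry_frayed(land, data, config, polish=polish)
    return land


def _neighbor_median(land: SSELandscape, pair: ExponentPair) -> float:
    s = land.grid.spacing
    vals = []
    for da in (-s, 0.0, s):
        for db in (-s, 0.0, s):
            if da == 0.0 and db == 0.0:
                continue
            nb = (_snap(pair.a + da, s), _snap(pair.b + db, s))
            try:
                npair = ExponentPair(*nb)
            except ValueError:
                continue
            fr = land.entries.get(npair)
            if fr is not None and np.isfinite(fr.sse):
                vals.append(fr.sse)
    return float(np.median(vals)) if vals else np.nan


def frayed_entries(land: SSELandscape, *, zone_limit: float = 3.0,
                   factor: float = 0.5) -> list[ExponentPair]:
    """Grid points whose SSE sticks out from their neighborhood.

    A point in the zone a, b <= `zone_limit` is flagged when its SSE
    differs from the median of its (up to 8) neighbors by more than
    `factor` relative — the signature of an annealing run stuck far from
    the pair's true optimum ("frayed" near-optimal plots).
    """
    bad = []
    for pair, fr in land.entries.items():
        if pair.a > zone_limit or pair.b > zone_limit:
            continue
        med = _neighbor_median(land, pair)
        if not np.isfinite(med) or med <= 0:
            continue
        if not np.isfinite(fr.sse) or abs(fr.sse - med) > factor * med:
            bad.append(pair)
    return bad


def _best_neighbor_params(land: SSELandscape, pair: ExponentPair):
    s = land.grid.spacing
    best = None
    for da in (-s, 0.0, s):
        for db in (-s, 0.0, s):
            if da == 0.0 and db == 0.0:
                continue
            try:
                npair = ExponentPair(_snap(pair.a + da, s),
                                     _snap(pair.b + db, s))
            except ValueError:
                continue
            fr = land.entries.get(npair)
            if fr is not None and np.isfinite(fr.sse) and \
                    (best is None or fr.sse < best.sse):
                best = fr
    return None if best is None else best.params


def _retry_frayed(land: SSELandscape, data, config, *, polish: bool,
                  budget_factor: float = 5.0, max_passes: int = 3) -> None:
    for attempt in range(max_passes):
        bad = frayed_entries(land)
        if not bad:
            return
        improved = False
        for pair in bad:
            cands = []
            start = _best_neighbor_params(land, pair)
            if start is not None:
                cfg = config.with_seed(
                    _pair_seed(config.seed, pair.a, pair.b,
                               salt=2 + attempt))
                cands.append(fit_pair(pair, data, cfg, start=start,
                                      warm=True, polish=polish))
            if attempt == 0:
                cfg = config.scaled(1.0 / budget_factor)
                cfg = cfg.with_seed(_pair_seed(config.seed, pair.a, pair.b,
                                               salt=1))
                cands.append(fit_pair(pair, data, cfg, start=None,
                                      polish=polish))
            for fr in cands:
                if fr.sse < land.entries[pair].sse:
                    land.entries[pair] = fr
                    improved = True
        if not improved:
            return


def extend_if_boundary(land: SSELandscape, data: GrowthDataset,
                       config: AnnealConfig | None = None, *,
                       increment: float = 0.5, a_cap: float = 4.0,
                       b_cap: float = 12.0, polish: bool = True
                       ) -> SSELandscape:
    """Grow the grid while the best pair sits on its b- or a-boundary.

    New b-columns warm-start from the rightmost existing fit of their
    row; new a-rows are swept cold.  If a cap is hit while the optimum
    still touches the boundary, the landscape is returned with
    ``optimality_secured=False`` (the optimum could lie outside the
    searched region).
    """
    config = config or AnnealConfig()
    grid = land.grid
    entries = dict(land.entries)
    secured = True
    while True:
        cur = SSELandscape(entries, grid, land.data_label)
        bp, _ = cur.best()
        s = grid.spacing
        on_b = abs(bp.b - _snap(grid.b_max, s)) < s / 2
        on_a = abs(bp.a - _snap(grid.a_max, s)) < s / 2
        if not (on_a or on_b):
            break
        if (on_b and grid.b_max >= b_cap - 1e-9) or \
                (on_a and grid.a_max >= a_cap - 1e-9):
            secured = False
            warnings.warn(
                f"optimum {bp} still on the grid boundary at the extension "
                f"cap; optimality not secured")
            break
        if on_b:
            new_b_max = min(round(grid.b_max + increment, 10), b_cap)
            new_grid = replace(grid, b_max=new_b_max)
            for a in new_grid.a_values():
                old_bs = grid.b_values(a)
                new_bs = [b for b in new_grid.b_values(a)
                          if b > grid.b_max + 1e-9]
                if not new_bs:
                    continue
                start = None
                if old_bs.size:
                    prev = entries.get(ExponentPair(a, old_bs[-1]))
                    start = prev.params if prev is not None else None
                entries.update(_fit_row(a, np.array(new_bs), data, config,
                                        start, polish))
            grid = new_grid
        else:
            new_a_max = min(round(grid.a_max + increment, 10), a_cap)
            new_grid = replace(grid, a_max=new_a_max)
            for a in new_grid.a_values():
                if a <= grid.a_max + 1e-9:
                    continue
                b_vals = new_grid.b_values(a)
                if b_vals.size:
                    entries.update(_fit_row(a, b_vals, data, config, None,
                                            polish))
            grid = new_grid
    out = SSELandscape(entries, grid, land.data_label,
                       optimality_secured=secured)
    return out


# --- thin functional aliases -------------------------------------------------

def near_optimal_region(land: SSELandscape, threshold: float
                        ) -> set[ExponentPair]:
    """Pairs whose SSE_opt exceeds the landscape minimum by at most
    `threshold` (relative); always contains the best pair."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return land.near_optimal(threshold)


def best_pair(land: SSELandscape) -> tuple[ExponentPair, FitResult]:
    """The landscape argmin with deterministic lexicographic tie-break."""
    return land.best()
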