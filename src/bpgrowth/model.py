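"""Model/Results front end, in the statsmodels idiom.

`BertalanffyPutter` binds a growth dataset to one exponent pair;
``fit()`` runs the annealing + polish optimization and returns
`BertalanffyPutterResults`, which carries the estimates, diagnostics,
prediction machinery and a ``summary()`` table.  The grid-level API
(`bpgrowth.landscape`) produces many such fits at once; this class is
the single-model view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import GrowthDataset, generate_synthetic
from .diagnostics import ResidualReport, prediction_band, residual_report
from .fitting import AnnealConfig, FitResult, fit_pair, sse_of
from .ode import (BPParameters, ExponentPair, asymptotic_volume,
                  inflection_volume, relative_growth_rate, solve_curve)

__all__ = ["BertalanffyPutter", "BertalanffyPutterResults"]


class BertalanffyPutter:
    """Bertalanffy-Putter growth model dv/dt = p v^a - q v^b for one
    fixed exponent pair, to be fitted to size-at-age data.

    Parameters
    ----------
    data : GrowthDataset
        Observations (days, mm^3).
    pair : ExponentPair or tuple
        The exponents (a, b), 0 <= a < b.

    Examples
    --------
    >>> from bpgrowth import BertalanffyPutter, load_dataset
    >>> model = BertalanffyPutter(load_dataset("paper"), (1.62, 2.44))
    >>> res = model.fit(seed=1)
    >>> round(res.sse / 1e5, 2)
    1.27
    """

    def __init__(self, data: GrowthDataset, pair):
        if not isinstance(pair, ExponentPair):
            pair = ExponentPair(*pair)
        self.data = data
        self.pair = pair

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pair, *, time_col: str = "time",
                       volume_col: str = "volume", label: str = ""
                       ) -> "BertalanffyPutter":
        data = GrowthDataset(df[time_col].to_numpy(float),
                             df[volume_col].to_numpy(float), label=label)
        return cls(data, pair)

    def sse(self, params: BPParameters) -> float:
        """The objective at given parameters (sum of squared mm^3 errors)."""
        return sse_of(params, self.data)

    def fit(self, config: AnnealConfig | None = None, *, seed=None,
            start: BPParameters | None = None, polish: bool = True
            ) -> "BertalanffyPutterResults":
        """Anneal + polish fit of (p, q, v0); seeded and reproducible."""
        config = config or AnnealConfig()
        if seed is not None:
            config = config.with_seed(seed)
        fr = fit_pair(self.pair, self.data, config, start=start,
                      polish=polish)
        return BertalanffyPutterResults(self, fr)

    def simulate(self, params: BPParameters, *, noise_sd: float = 0.0,
                 seed=None, times=None) -> GrowthDataset:
        """Synthetic dataset from a given curve at the model's times."""
        t = self.data.times if times is None else times
        return generate_synthetic(params, t, noise_sd, seed)


class BertalanffyPutterResults:
    """Fit results for one exponent pair; statsmodels-results flavored."""

    def __init__(self, model: BertalanffyPutter, fit: FitResult):
        self.model = model
        self._fit = fit

    # -- estimates ----------------------------------------------------------
    @property
    def params(self) -> BPParameters:
        return self._fit.params

    @property
    def sse(self) -> float:
        return self._fit.sse

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    @property
    def nobs(self) -> int:
        return len(self.model.data)

    @property
    def fittedvalues(self) -> np.ndarray:
        return solve_curve(self.params, self.model.data.times)

    @property
    def resid(self) -> np.ndarray:
        return self.model.data.volumes - self.fittedvalues

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.resid, ddof=1))

    @property
    def asymptotic_volume(self) -> float:
        return asymptotic_volume(self.params)

    @property
    def inflection_volume(self) -> float:
        return inflection_volume(self.params)

    # -- prediction ---------------------------------------------------------
    def predict(self, times=None) -> np.ndarray:
        t = self.model.data.times if times is None else times
        return solve_curve(self.params, t)

    def relative_growth_rate(self, times=None) -> np.ndarray:
        t = self.model.data.times if times is None else times
        return relative_growth_rate(self.params, t)

    def prediction_band(self, confidence: float = 0.95, times=None):
        return prediction_band(self._fit, self.model.data, confidence, times)

    def residual_report(self, **kw) -> ResidualReport:
        return residual_report(self._fit, self.model.data, **kw)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        pm = self.params
        lines = [
            "Bertalanffy-Putter growth model results",
            "=" * 47,
            f"{'Dataset:':<22}{self.model.data.label or '<unnamed>'}",
            f"{'Observations:':<22}{self.nobs}",
            f"{'Exponent pair (a, b):':<22}({pm.a:g}, {pm.b:g})",
            f"{'p (growth coeff.):':<22}{pm.p:.6g}",
            f"{'q (decay coeff.):':<22}{pm.q:.6g}",
            f"{'v0 (mm^3):':<22}{pm.v0:.6g}",
            f"{'SSE (mm^6):':<22}{self.sse:.5g}",
            f"{'Residual SD (mm^3):':<22}{self.residual_sd:.4g}",
            f"{'Asymptote (mm^3):':<22}{self.asymptotic_volume:.5g}",
        ]
        if pm.a > 0:
            lines.append(
                f"{'Inflection (mm^3):':<22}{self.inflection_volume:.5g}")
        lines += [
            f"{'Polished:':<22}{self._fit.polished}",
            f"{'Annealing steps:':<22}{self._fit.anneal_steps}",
            f"{'Seed:':<22}{self._fit.seed}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200, confidence: float = 0.95):
        """Data, fitted curve and prediction band on one axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        tg = np.linspace(d.times[0], d.times[-1], n_grid)
        curve, lo, hi = self.prediction_band(confidence, tg)
        ax.fill_between(tg, lo, hi, alpha=0.25, label=f"{confidence:.0%} band")
        ax.plot(tg, curve, label="fitted curve")
        ax.plot(d.times, d.volumes, "ko", label="data")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("volume (mm$^3$)")
        ax.legend()
        return ax
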