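"""Size-at-age datasets: container, CSV I/O, the built-in breast-cancer
xenograft series, and a synthetic-curve generator for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ode import BPParameters, solve_curve

__all__ = ["GrowthDataset", "load_dataset", "paper_dataset",
           "generate_synthetic"]

# Average volumes (mm^3) of untreated GI-101A human breast cancer
# xenografts in nude mice, measured at 14 time points over 114 days;
# digitized from the published growth plot of the original experiment.
_XENOGRAFT_TABLE = (
    (0, 225), (9, 300), (20, 582), (32, 650), (43, 680), (54, 930),
    (65, 1225), (76, 1464), (82, 1911), (87, 2184), (93, 2570),
    (98, 2721), (107, 2948), (114, 3503),
)


@dataclass(frozen=True)
class GrowthDataset:
    """Ordered (time, volume) observations; days and mm^3 throughout."""

    times: np.ndarray
    volumes: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and volumes must be 1-D of equal length")
        if t.size < 2:
            raise ValueError("need at least 2 observations")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise ValueError("missing or non-finite values are not allowed")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def t_span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def truncated(self, cutoff_time: float, label: str | None = None
                  ) -> "GrowthDataset":
        """The initial segment with observation times <= cutoff_time."""
        keep = self.times <= cutoff_time
        if keep.sum() < 2:
            raise ValueError(
                f"cutoff {cutoff_time} leaves fewer than 2 observations")
        return GrowthDataset(self.times[keep], self.volumes[keep],
                             label if label is not None
                             else f"{self.label}[<= {cutoff_time:g} d]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "volume": self.volumes})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def paper_dataset() -> GrowthDataset:
    """The built-in 14-point untreated-tumor series (114 days)."""
    t, v = zip(*_XENOGRAFT_TABLE)
    return GrowthDataset(np.array(t, float), np.array(v, float),
                         label="GI-101A xenograft")


def load_dataset(source, label: str | None = None) -> GrowthDataset:
    """Load a growth dataset from CSV (columns ``time``, ``volume``).

    ``source`` may also be the keyword ``"paper"`` for the built-in
    xenograft series.
    """
    if isinstance(source, str) and source.lower() == "paper":
        return paper_dataset()
    try:
        df = pd.read_csv(source)
    except Exception as exc:
        raise ValueError(f"could not parse {source!r} as CSV: {exc}") from exc
    cols = {c.lower().strip(): c for c in df.columns}
    if "time" not in cols or "volume" not in cols:
        raise ValueError(
            f"CSV must have columns 'time' and 'volume'; found {list(df.columns)}")
    return GrowthDataset(df[cols["time"]].to_numpy(float),
                         df[cols["volume"]].to_numpy(float),
                         label=label or str(source))


def generate_synthetic(params: BPParameters, times, noise_sd: float,
                       seed=None, label: str | None = None) -> GrowthDataset:
    """Sample a growth curve at `times` with additive Gaussian noise.

    Noisy volumes are truncated below at a small positive floor so the
    result is a valid dataset; if more than 10% of points needed
    truncation the noise level is unreasonably large for the curve and a
    warning is emitted.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    v = solve_curve(params, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = v + rng.normal(0.0, noise_sd, size=v.shape)
    else:
        noisy = v.copy()
    floor = 1e-6 * max(float(v.max()), 1.0)
    n_trunc = int(np.sum(noisy < floor))
    if n_trunc > 0.1 * t.size:
        warnings.warn(
            f"{n_trunc}/{t.size} synthetic volumes were truncated to stay "
            f"positive; noise_sd={noise_sd} is large for this curve")
    noisy = np.maximum(noisy, floor)
    return GrowthDataset(t, noisy, label=label or
                         f"synthetic(a={params.a:g}, b={params.b:g}, "
                         f"noise={noise_sd:g})")
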