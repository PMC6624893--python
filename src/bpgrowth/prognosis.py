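"""Prognosis: fit initial data segments, extrapolate, and score forecasts.

The predictive-power experiment truncates the series to its first
observations (e.g. the first 65 of 114 days), runs the full
exponent-grid search on the segment, and then evaluates the fitted
curve — unchanged — against the complete series.  The segment SSE
measures interpolation quality; the all-data SSE measures forecast
quality.  The horizon assessment turns the per-point extrapolation
errors into "how many days past the cutoff was the forecast usable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GrowthDataset
from .fitting import AnnealConfig, FitResult, sse_of
from .landscape import GridSpec, SSELandscape, extend_if_boundary, sweep
from .ode import CurveSolutionError, solve_curve

__all__ = ["SegmentSpec", "PrognosisReport", "fit_segment",
           "extrapolation_sse", "horizon_assessment", "reports_to_frame"]

#: the model has 5 free parameters overall (a, b, p, q, v0); fitting a
#: segment with fewer than this many observations is refused
MIN_SEGMENT_POINTS = 4


@dataclass(frozen=True)
class SegmentSpec:
    """An initial data segment: observations with t <= cutoff_time (days)."""

    cutoff_time: float
    label: str = ""

    def apply(self, data: GrowthDataset) -> GrowthDataset:
        seg = data.truncated(self.cutoff_time,
                             label=self.label or None)
        if len(seg) < MIN_SEGMENT_POINTS:
            raise ValueError(
                f"segment to {self.cutoff_time:g} d keeps only {len(seg)} "
                f"observations; at least {MIN_SEGMENT_POINTS} are required "
                f"for a 5-parameter model family")
        return seg


@dataclass(frozen=True)
class PrognosisReport:
    """Outcome of fitting one segment and extrapolating to the full data."""

    segment: SegmentSpec
    best: FitResult
    sse_segment: float
    sse_all: float
    times_all: np.ndarray
    residuals_all: np.ndarray  # observed - predicted over the full series

    @property
    def horizon(self) -> float:
        """Days past the cutoff with relative error below 15% (default)."""
        return self.horizon_at(0.15)

    def horizon_at(self, tolerance: float) -> float:
        """Longest time past the cutoff over which every observed point is
        predicted within `tolerance` relative volume error."""
        t = self.times_all
        cut = self.segment.cutoff_time
        future = t > cut
        if not future.any():
            return 0.0
        pred_err = np.abs(self.residuals_all[future])
        rel = pred_err / self._future_volumes
        good = rel < tolerance
        horizon = 0.0
        for ti, ok in zip(t[future], good):
            if not ok:
                break
            horizon = ti - cut
        return float(horizon)

    @property
    def _future_volumes(self) -> np.ndarray:
        cut = self.segment.cutoff_time
        return self._volumes_all[self.times_all > cut]

    # set in __post_init__-free style by fit_segment / make_report
    _volumes_all: np.ndarray = None  # type: ignore[assignment]


def extrapolation_sse(fit: FitResult, full_data: GrowthDataset) -> float:
    """SSE of a segment-fitted curve over ALL observations, without refit.

    The curve keeps the segment's anchoring (v(t1) = v0 at the first
    observation, which the truncation preserves).  Integration failure
    over the longer horizon yields +inf.
    """
    s = sse_of(fit.params, full_data)
    return float(s)


def make_report(segment: SegmentSpec, fit: FitResult,
                full_data: GrowthDataset) -> PrognosisReport:
    """Assemble the extrapolation residuals and SSEs for one segment fit."""
    try:
        pred = solve_curve(fit.params, full_data.times)
        resid = full_data.volumes - pred
        sse_all = float(np.sum(resid ** 2))
    except CurveSolutionError:
        resid = np.full(len(full_data), np.nan)
        sse_all = np.inf
    rep = PrognosisReport(segment, fit, fit.sse, sse_all,
                          full_data.times.copy(), resid)
    object.__setattr__(rep, "_volumes_all", full_data.volumes.copy())
    return rep


def fit_segment(data: GrowthDataset, segment: SegmentSpec,
                grid: GridSpec | None = None,
                config: AnnealConfig | None = None, *,
                extend: bool = True, polish: bool = True
                ) -> tuple[SSELandscape, PrognosisReport]:
    """Grid-sweep the truncated dataset and score its best model on the
    full series."""
    seg = segment.apply(data)
    grid = grid or GridSpec()
    config = config or AnnealConfig()
    land = sweep(grid, seg, config, polish=polish)
    if extend:
        land = extend_if_boundary(land, seg, config, polish=polish)
    _, fit = land.best()
    return land, make_report(segment, fit, data)


def horizon_assessment(reports: list[PrognosisReport],
                       tolerance: float = 0.15) -> dict:
    """Usable forecast horizon per segment plus the median across segments.

    For each report, the horizon is the longest time past the cutoff for
    which every observed point is predicted within `tolerance` relative
    volume error (an empty horizon is 0 days).
    """
    if not reports:
        raise ValueError("need at least one report")
    per = {rep.segment.cutoff_time: rep.horizon_at(tolerance)
           for rep in reports}
    return {"per_segment": per,
            "median": float(np.median(list(per.values()))),
            "tolerance": tolerance}


def reports_to_frame(reports: list[PrognosisReport]) -> pd.DataFrame:
    """Summary table: one row per segment, mirroring the standard
    (cutoff, a, b, v0, p, q, sse_segment, sse_all) layout."""
    recs = []
    for rep in reports:
        pm = rep.best.params
        recs.append((rep.segment.cutoff_time, pm.a, pm.b, pm.v0, pm.p, pm.q,
                     rep.sse_segment, rep.sse_all))
    return pd.DataFrame(recs, columns=["cutoff", "a", "b", "v0", "p", "q",
                                       "sse_segment", "sse_all"])
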