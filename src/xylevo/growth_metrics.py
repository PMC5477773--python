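"""Growth-curve parameter extraction and evolved/ancestor fold changes.

Plate-reader OD600 time series are summarised by four numbers per curve:

* ``log_growth_rate`` — maximal specific growth rate, i.e. the largest
  least-squares slope of ln(OD) over a sliding window (per hour);
* ``max_od`` — maximal (smoothed) optical density reached;
* ``time_to_max_od`` — earliest time the smoothed curve reaches a
  configurable fraction of the maximum (hours);
* ``effective_growth_rate`` — max_od / time_to_max_od (OD per hour), a
  single metric combining yield and speed of growth.

Fold changes (evolved / wild type) of these metrics, and the count of
strains whose effective growth rate improved, summarise an adaptive
evolution experiment in which strains are propagated by serial dilution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthMetricSet",
    "FoldChangeRecord",
    "MetricsConfig",
    "smooth_curve",
    "compute_metrics",
    "fold_change",
    "classify_improvement",
    "generations_elapsed",
]

METRIC_NAMES = ("log_growth_rate", "max_od", "time_to_max_od", "effective_growth_rate")


class DegenerateCurveWarning(UserWarning):
    """Raised as a warning when a curve shows no net growth."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's ordered (time, OD) series.

    Invariants: at least 4 timepoints, strictly increasing times,
    strictly positive OD values.
    """

    strain_id: str
    status: str  # "wt" | "evolved"
    replicate: int
    times: np.ndarray
    ods: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ods = np.asarray(self.ods, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ods", ods)
        if self.status not in ("wt", "evolved"):
            raise ValueError(f"status must be 'wt' or 'evolved', got {self.status!r}")
        if times.ndim != 1 or ods.shape != times.shape:
            raise ValueError("times and ods must be 1-D arrays of equal length")
        if len(times) < 4:
            raise ValueError("a growth curve needs at least 4 timepoints")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(ods > 0):
            raise ValueError("all OD values must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthMetricSet:
    log_growth_rate: float
    max_od: float
    time_to_max_od: float
    effective_growth_rate: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldChangeRecord:
    """Per-strain evolved/wt ratios of the four growth metrics."""

    strain_id: str
    log_growth_rate: float
    max_od: float
    time_to_max_od: float
    effective_growth_rate: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsConfig:
    """Tunables for metric extraction.

    smoothing_window: odd window for median+mean smoothing (points).
    slope_window: points per sliding ln(OD) regression window.
    saturation_fraction: fraction of max smoothed OD defining the
        saturation time; 1.0 means the time of the maximum itself.
    """

    smoothing_window: int = 5
    slope_window: int = 5
    saturation_fraction: float = 0.95

    def __post_init__(self):
        if self.smoothing_window % 2 == 0 or self.smoothing_window < 1:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.slope_window < 2:
            raise ValueError("slope_window must be >= 2")
        if not 0 < self.saturation_fraction <= 1.0:
            raise ValueError("saturation_fraction must be in (0, 1]")


def smooth_curve(curve: GrowthCurve, window: int) -> GrowthCurve:
    """Running-median then running-mean smoothing.

    Endpoint windows are truncated to the available points; ``window=1``
    is the identity. ``window`` must be odd.
    """
    if window < 1 or window > len(curve):
        raise ValueError("window must be >= 1 and <= series length")
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window == 1:
        return curve
    s = pd.Series(curve.ods)
    med = s.rolling(window, center=True, min_periods=1).median()
    smoothed = med.rolling(window, center=True, min_periods=1).mean()
    return replace(curve, ods=smoothed.to_numpy())


def _max_sliding_slope(times: np.ndarray, log_od: np.ndarray, window: int) -> float:
    """Maximum least-squares slope of log_od vs time over sliding windows."""
    n = len(times)
    window = min(window, n)
    tw = np.lib.stride_tricks.sliding_window_view(times, window)
    yw = np.lib.stride_tricks.sliding_window_view(log_od, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    denom = (tc * tc).sum(axis=1)
    slopes = (tc * yc).sum(axis=1) / denom
    return float(np.max(slopes))


def compute_metrics(curve: GrowthCurve, config: MetricsConfig | None = None) -> GrowthMetricSet:
    """Extract the four growth metrics from one curve.

    A curve whose smoothed maximum does not exceed its first value is
    flagged degenerate: metrics are still reported (with a warning) so
    batch runs complete.
    """
    config = config or MetricsConfig()
    sm = smooth_curve(curve, min(config.smoothing_window, _largest_odd(len(curve))))
    ods = sm.ods
    times = sm.times

    max_od = float(np.max(ods))
    degenerate = max_od <= ods[0]
    if degenerate:
        warnings.warn(
            f"curve {curve.strain_id}/{curve.status} shows no net growth",
            DegenerateCurveWarning,
            stacklevel=2,
        )

    threshold = config.saturation_fraction * max_od
    # earliest index at/above the saturation threshold (earliest argmax
    # when saturation_fraction == 1, since the comparison is >=)
    idx = int(np.argmax(ods >= threshold - 1e-12))
    time_to_max = float(times[idx])

    rate = _max_sliding_slope(times, np.log(np.maximum(ods, 1e-12)), config.slope_window)

    eff = max_od / time_to_max if time_to_max > 0 else math.nan
    return GrowthMetricSet(
        log_growth_rate=rate,
        max_od=max_od,
        time_to_max_od=time_to_max,
        effective_growth_rate=eff,
        degenerate=degenerate,
    )


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def fold_change(evolved: GrowthMetricSet, wt: GrowthMetricSet, strain_id: str = "") -> FoldChangeRecord:
    """Element-wise evolved/wt ratio of the four metrics.

    By construction the effective-growth-rate fold equals
    (max_od fold) / (time_to_max_od fold).
    """
    for name in METRIC_NAMES:
        if getattr(wt, name) == 0:
            raise ZeroDivisionError(f"wild-type metric {name!r} is zero")
    return FoldChangeRecord(
        strain_id=strain_id,
        **{name: getattr(evolved, name) / getattr(wt, name) for name in METRIC_NAMES},
    )


def classify_improvement(
    records: list[FoldChangeRecord], threshold: float = 1.0
) -> tuple[dict[str, str], int]:
    """Label each strain improved/not_improved by its effective-growth fold.

    A strain is improved iff its effective-growth-rate fold is strictly
    greater than ``threshold``. Returns (labels by strain, improved count).
    """
    if not records:
        raise ValueError("no fold-change records given")
    labels = {
        rec.strain_id: ("improved" if rec.effective_growth_rate > threshold else "not_improved")
        for rec in records
    }
    return labels, sum(1 for v in labels.values() if v == "improved")


def generations_elapsed(dilution_factor: float, n_dilutions: int) -> float:
    """Generations under serial propagation: n_dilutions * log2(dilution_factor).

    Each batch cycle regrows the culture by the dilution factor, i.e.
    log2(factor) doublings per cycle (a 1:64 dilution gives 6 generations).
    """
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n_dilutions < 0:
        raise ValueError("number of dilutions must be non-negative")
    return n_dilutions * math.log2(dilution_factor)
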