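"""Reproducibility, error propagation, sensitivity linearity and
baseline-relative trend analysis.

These are the evaluation tools wrapped around the QA analyses: repeated-
measurement standard deviations propagated through ratio/difference
metrics, ordinary-least-squares fits of measured vs. injected deviations,
and longitudinal drift of two devices each normalized to its first
(baseline) measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ReproResult:
    """Sample SD of n repeated measurements (n-1 denominator)."""

    n: int
    sd: float
    propagated_sd: float | None = None


@dataclass(frozen=True)
class LinearityResult:
    """OLS slope/intercept and Pearson r of measured vs. injected deltas."""

    slope: float
    intercept: float
    r: float
    degenerate: bool = False

    def predict(self, injected_change: float) -> float:
        """Reported change the fit predicts for a given reference change."""
        return self.slope * injected_change + self.intercept


@dataclass(frozen=True)
class TrendSeries:
    """Baseline-relative drift of each device plus paired differences."""

    timestamps: tuple
    deltas: dict[str, np.ndarray]
    differences: np.ndarray | None
    mean_difference: float | None
    sd_difference: float | None


def reproducibility(values) -> ReproResult:
    """Sample standard deviation of repeated measurements."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two repeated measurements")
    return ReproResult(n=v.size, sd=float(np.std(v, ddof=1)))


def propagate_ratio(a_mean: float, a_sd: float, b_mean: float, b_sd: float) -> float:
    """SD of a/b for uncorrelated a, b (first-order propagation):
    sqrt((a_sd/b)^2 + (a*b_sd/b^2)^2)."""
    if b_mean == 0:
        raise ZeroDivisionError("denominator mean must be nonzero")
    if a_sd < 0 or b_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(a_sd / b_mean, a_mean * b_sd / b_mean ** 2))


def propagate_difference(a_sd: float, b_sd: float) -> float:
    """SD of a - b for uncorrelated a, b: sqrt(a_sd^2 + b_sd^2)."""
    if a_sd < 0 or b_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(a_sd, b_sd))


def sensitivity_fit(injected, measured, baseline_subtract: bool = True) -> LinearityResult:
    """OLS fit of measured vs. injected deviations.

    With ``baseline_subtract`` (default) the first entry of each vector is
    subtracted first, mirroring relative-to-baseline sensitivity analyses.
    A constant measured vector yields a degenerate result (r undefined).
    """
    x = np.asarray(injected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("injected and measured must be matching 1-D vectors (n >= 2)")
    if baseline_subtract:
        x = x - x[0]
        y = y - y[0]
    if np.ptp(x) == 0:
        raise ValueError("injected values are constant; no fit possible")
    if np.ptp(y) == 0:
        return LinearityResult(slope=0.0, intercept=float(y[0]), r=float("nan"),
                               degenerate=True)
    fit = sps.linregress(x, y)
    return LinearityResult(slope=float(fit.slope), intercept=float(fit.intercept),
                           r=float(fit.rvalue))


def trend(series: pd.DataFrame) -> TrendSeries:
    """Baseline-relative drift per device and paired device differences.

    ``series`` is long-form with columns (timestamp, device, value). Per
    device, delta_t = 100*(m_t/m_1 - 1) relative to its first measurement.
    With exactly two devices the paired differences (first minus second,
    in column order of appearance) and their mean +/- SD are reported;
    time points missing for either device are dropped with a warning.
    """
    required = {"timestamp", "device", "value"}
    if not required.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(required)}")
    wide = series.pivot_table(index="timestamp", columns="device",
                              values="value", sort=True)
    # preserve device order of first appearance
    devices = list(dict.fromkeys(series["device"]))
    deltas: dict[str, np.ndarray] = {}
    for dev in devices:
        col = wide[dev].dropna()
        if col.empty:
            raise ValueError(f"device {dev!r} has no measurements")
        base = col.iloc[0]
        if base == 0:
            raise ZeroDivisionError(f"device {dev!r} baseline is zero")
        deltas[dev] = 100.0 * (col.to_numpy() / base - 1.0)

    differences = mean_diff = sd_diff = None
    if len(devices) == 2:
        a, b = devices
        da = pd.Series(deltas[a], index=wide[a].dropna().index)
        db = pd.Series(deltas[b], index=wide[b].dropna().index)
        joined = pd.concat([da, db], axis=1, keys=[a, b])
        if joined.isna().any().any():
            warnings.warn("dropping time points missing for one device",
                          stacklevel=2)
            joined = joined.dropna()
        differences = (joined[a] - joined[b]).to_numpy()
        if differences.size > 1:
            mean_diff = float(differences.mean())
            sd_diff = float(differences.std(ddof=1))
    return TrendSeries(timestamps=tuple(wide.index), deltas=deltas,
                       differences=differences, mean_difference=mean_diff,
                       sd_difference=sd_diff)
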