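"""Descriptive and inferential statistics for the quantification pipeline.

Box-whisker summaries use inclusive linear-interpolation quartiles and the
1.5 x IQR outlier fence; group comparisons use the two-tailed Student t-test
(equal-variance by default, Welch behind a flag); trend strength is ordinary
least squares R²; spindle time-lapse traces are scored for anaphase duration
as the time between the onset of rapid spindle elongation and spindle
breakdown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class BoxWhiskerSummary:
    """Quartiles, 1.5-IQR whiskers and outliers of one distribution."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]
    n: int

    def to_dict(self) -> dict:
        return {
            "median": self.median, "q1": self.q1, "q3": self.q3,
            "whisker_low": self.whisker_low, "whisker_high": self.whisker_high,
            "outliers": list(self.outliers), "n": self.n,
        }


@dataclass
class SpindleTrace:
    """Spindle length vs time for one cell, with scored events once computed."""

    time_min: np.ndarray
    length_um: np.ndarray
    onset_min: float | None = None
    breakdown_min: float | None = None
    duration_min: float | None = None
    truth: dict | None = None


@dataclass
class AnaphaseScore:
    """Result of scoring one spindle trace."""

    onset_min: float | None
    breakdown_min: float | None
    duration_min: float | None
    censored: bool
    reason: str | None  # "no onset" / "no breakdown" when unresolved


def box_whisker_summary(values) -> BoxWhiskerSummary:
    """Summarize a distribution for a box-whisker plot.

    Quartiles use inclusive linear interpolation; the fences sit at
    q1 - 1.5*IQR and q3 + 1.5*IQR; the whiskers are the extreme data values
    inside the fences and every point outside them is an outlier.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(
            f"box-whisker summary needs at least 4 values, got {x.size}")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    outliers = x[(x < lo) | (x > hi)]
    return BoxWhiskerSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers), n=int(x.size),
    )


def students_t_two_tailed(a, b, equal_variance: bool = True) -> float:
    """Two-tailed Student t-test p-value between two samples.

    Degenerate zero-variance inputs are resolved explicitly: identical
    constant groups give p = 1, separated constant groups give the p -> 0
    limit (returned as 0.0 with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs n >= 2 in both groups")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        logger.warning(
            "zero-variance groups with unequal means: p-value is a 0 limit")
        return 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.pvalue)


def linear_trend_r2(x, y) -> tuple[float, float, float]:
    """Ordinary-least-squares trend line: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("trend fit needs n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x is constant; trend line undefined")
    if np.all(y == y[0]):
        # a flat response has no explainable variance: r^2 is 0 by definition
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def normalize_max_to_one(values) -> np.ndarray:
    """Divide a set of intensities by its maximum (order-preserving)."""
    x = np.asarray(values, dtype=float)
    m = x.max()
    if not m > 0:
        raise ValueError(f"maximum must be positive to normalize, got {m}")
    return x / m


def classify_spb_pair(intensity_a: float, intensity_b: float
                      ) -> tuple[float, float, bool]:
    """Order a cell's two SPB intensities as (SPB1, SPB2) = (bright, dim).

    Ties keep the input order and set the tie flag (third return value).
    """
    if intensity_a < 0 or intensity_b < 0:
        raise ValueError("SPB intensities must be non-negative")
    if intensity_a == intensity_b:
        logger.warning("tied SPB intensities %s; keeping input order",
                       intensity_a)
        return intensity_a, intensity_b, True
    if intensity_a >= intensity_b:
        return intensity_a, intensity_b, False
    return intensity_b, intensity_a, False


def anaphase_duration(trace: SpindleTrace,
                      rate_threshold_um_per_min: float = 0.5,
                      collapse_fraction: float = 0.5) -> AnaphaseScore:
    """Score one spindle-length trace for anaphase duration.

    Onset is the first timepoint whose centered sliding-window elongation
    rate exceeds ``rate_threshold_um_per_min``; breakdown is the first later
    timepoint whose length drops below ``collapse_fraction`` times the
    running maximum length; duration is their difference.  Traces without a
    detectable onset or breakdown return a censored score with the reason.
    """
    if rate_threshold_um_per_min <= 0 or collapse_fraction <= 0:
        raise ValueError("thresholds must be positive")
    t = np.asarray(trace.time_min, dtype=float)
    length = np.asarray(trace.length_um, dtype=float)
    if t.size != length.size or t.size < 3:
        raise ValueError("trace needs matching time/length with >= 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")

    # centered 3-point elongation rate
    rate = np.full(t.shape, np.nan)
    rate[1:-1] = (length[2:] - length[:-2]) / (t[2:] - t[:-2])
    onset_idx = None
    for i in range(1, t.size - 1):
        if rate[i] > rate_threshold_um_per_min:
            onset_idx = i
            break
    if onset_idx is None:
        return AnaphaseScore(None, None, None, censored=True,
                             reason="no onset")

    running_max = np.maximum.accumulate(length)
    breakdown_idx = None
    for i in range(onset_idx + 1, t.size):
        if length[i] < collapse_fraction * running_max[i - 1]:
            breakdown_idx = i
            break
    onset = float(t[onset_idx])
    if breakdown_idx is None:
        return AnaphaseScore(onset, None, None, censored=True,
                             reason="no breakdown")
    breakdown = float(t[breakdown_idx])
    trace.onset_min = onset
    trace.breakdown_min = breakdown
    trace.duration_min = breakdown - onset
    return AnaphaseScore(onset, breakdown, breakdown - onset,
                         censored=False, reason=None)
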