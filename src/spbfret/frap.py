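"""FRAP trace normalization and single-exponential recovery fitting.

A FRAP experiment bleaches the fluorophores at one spot and follows the
return of fluorescence as unbleached molecules exchange in.  For
reaction-dominant binding, recovery is the single exponential

    I(t) = c + a * (1 - exp(-k t)),

with t counted from the first post-bleach frame.  The fitted rate k gives
the half-recovery time t_half = ln(2)/k; the asymptote c + a, compared with
the pre-bleach level, gives the mobile fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

# k grid for multi-start fitting; exponential fits are initialization-
# sensitive, so the best of several starts is kept
K_STARTS = (0.01, 0.05, 0.1, 0.5, 1.0)

# below this rate the trace is operationally "no recovery"
NO_RECOVERY_K = 1e-3


@dataclass
class FrapTrace:
    """Spot-intensity time series around one bleach event."""

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    reference_intensity: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if not 0 < self.bleach_index < self.time_s.size:
            raise ValueError(f"bleach_index {self.bleach_index} out of range")

    @property
    def pre_bleach_mean(self) -> float:
        return float(np.mean(self.intensity[:self.bleach_index]))


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters for one trace."""

    k_per_s: float
    t_half_s: float
    plateau_fraction: float   # fitted asymptote / pre-bleach level
    bleach_depth_fraction: float
    mobile_fraction: float
    r_squared: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.k_per_s, "t_half_s": self.t_half_s,
            "plateau_fraction": self.plateau_fraction,
            "bleach_depth_fraction": self.bleach_depth_fraction,
            "mobile_fraction": self.mobile_fraction,
            "r_squared": self.r_squared, "converged": self.converged,
        }


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Normalize a trace to its pre-bleach mean.

    Intensities are divided by the mean of the pre-bleach frames, so the
    pre-bleach level becomes ~1.  If an unbleached reference trace is
    attached, the trace is additionally divided frame-wise by the reference
    (normalized the same way), correcting for acquisition photobleaching.
    """
    if trace.bleach_index < 3:
        raise ValueError("need at least 3 pre-bleach frames to normalize")
    pre = trace.pre_bleach_mean
    if pre <= 0:
        raise ValueError(f"pre-bleach mean must be positive, got {pre}")
    intensity = trace.intensity / pre
    if trace.reference_intensity is not None:
        ref = np.asarray(trace.reference_intensity, dtype=float)
        if ref.shape != trace.intensity.shape:
            raise ValueError("reference trace length mismatch")
        ref_pre = float(np.mean(ref[:trace.bleach_index]))
        if ref_pre <= 0:
            raise ValueError("reference pre-bleach mean must be positive")
        intensity = intensity / (ref / ref_pre)
    return replace(trace, intensity=intensity, reference_intensity=None)


def _model(t, c, a, k):
    return c + a * (1.0 - np.exp(-k * t))


def fit_single_exponential(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit to the post-bleach frames.

    The trace is first normalized to its pre-bleach mean; the model
    ``c + a*(1 - exp(-k t))`` is fitted on post-bleach frames with t = 0 at
    the first post-bleach frame, multi-started over k.  A failed optimizer
    yields ``converged=False`` rather than an exception; an effectively flat
    recovery (k below 1e-3 /s) reports ``t_half_s = inf``.
    """
    norm = normalize_trace(trace)
    n_post = norm.time_s.size - norm.bleach_index
    if n_post < 5:
        raise ValueError("need at least 5 post-bleach frames to fit")
    t = norm.time_s[norm.bleach_index:] - norm.time_s[norm.bleach_index]
    y = norm.intensity[norm.bleach_index:]

    best = None
    for k0 in K_STARTS:
        try:
            popt, _ = curve_fit(
                _model, t, y, p0=(float(y[0]), max(1.0 - y[0], 0.1), k0),
                bounds=([-0.5, -0.5, 0.0], [1.5, 2.0, 20.0]),
                maxfev=10000)
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        return FrapFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                       math.nan, converged=False)
    (c, a, k), ssr = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))
    # no-recovery traces (flat, or vanishing amplitude) report t_half = inf;
    # with a ~ 0 the rate k is unidentifiable
    t_half = (math.log(2) / k
              if k > NO_RECOVERY_K and abs(a) > 1e-6 else math.inf)
    depth = 1.0 - c
    mobile = a / depth if depth > 1e-9 else math.nan
    return FrapFit(
        k_per_s=float(k), t_half_s=float(t_half),
        plateau_fraction=float(c + a), bleach_depth_fraction=float(depth),
        mobile_fraction=float(mobile), r_squared=r2, converged=True,
    )


def average_recovery_curve(traces: list[FrapTrace]
                           ) -> tuple[FrapTrace, np.ndarray]:
    """Average normalized traces on a shared time grid.

    All traces must share the same time vector and bleach index.  Returns
    the mean trace (which can itself be fitted) and the per-timepoint
    sample standard deviation (ddof=1; zeros for a single trace).
    """
    if not traces:
        raise ValueError("need at least one trace to average")
    first = traces[0]
    for tr in traces[1:]:
        if (tr.time_s.shape != first.time_s.shape
                or not np.allclose(tr.time_s, first.time_s)
                or tr.bleach_index != first.bleach_index):
            raise ValueError("traces are not on a common time grid")
    stack = np.stack([normalize_trace(tr).intensity for tr in traces])
    mean = stack.mean(axis=0)
    sd = (stack.std(axis=0, ddof=1) if stack.shape[0] > 1
          else np.zeros(mean.shape))
    return (FrapTrace(time_s=first.time_s.copy(), intensity=mean,
                      bleach_index=first.bleach_index), sd)
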