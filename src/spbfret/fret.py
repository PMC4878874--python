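"""Acceptor-photobleaching FRET efficiency quantification.

FRET between a donor and an acceptor fluorophore quenches the donor; if the
acceptor is destroyed by a targeted bleach pulse, the donor de-quenches.
The efficiency reported here is the percentage increase of the
background-corrected mean donor intensity at the spot after the bleach:

    FL_cor      = FL - FL_bg                       (background correction)
    E%          = 100 * (FL_cor_post - FL_cor_pre) / FL_cor_pre
    efficiency% = E% - median(E% of donor-only cells)

The donor-only control carries the donor fluorophore but no acceptor, so its
distribution of E% captures every acceptor-independent artifact (acquisition
photobleaching, drift); subtracting its median centers the null at exactly 0.
A protein pair is called FRET-positive when the normalized donor+acceptor
distribution is significantly higher than the donor-only one (two-tailed
Student t-test, p < 0.01, and a higher mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .stats import BoxWhiskerSummary, box_whisker_summary, students_t_two_tailed

logger = logging.getLogger(__name__)

DEFAULT_ROI_HALF_WIDTH = 2  # 5x5 px box: covers a diffraction-limited spot


@dataclass
class SpotROI:
    """Square measurement box centered on a detected spot."""

    center_px: tuple[int, int]      # (row, col)
    half_width_px: int
    mean_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.half_width_px < 1:
            raise ValueError("half_width_px must be >= 1")


@dataclass
class FretMeasurement:
    """Per-cell raw, background-corrected and percentage-increase values."""

    cell_id: str
    sample_class: str
    FL_pre: float
    FL_post: float
    FL_bg_pre: float
    FL_bg_post: float
    FL_cor_pre: float = field(init=False)
    FL_cor_post: float = field(init=False)
    E_pct: float | None = field(init=False, default=None)
    excluded_reason: str | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.FL_cor_pre = background_correct(self.FL_pre, self.FL_bg_pre)
        self.FL_cor_post = background_correct(self.FL_post, self.FL_bg_post)
        if self.FL_cor_pre > 0:
            self.E_pct = percent_increase(self.FL_cor_pre, self.FL_cor_post)
        else:
            self.excluded_reason = (
                f"non-positive corrected pre-bleach intensity "
                f"({self.FL_cor_pre:.3f})")
            logger.warning("cell %s excluded: %s", self.cell_id,
                           self.excluded_reason)


@dataclass
class FretPairResult:
    """Pooled, normalized efficiency distributions and the positive call."""

    pair_name: str
    efficiencies_DA_pct: np.ndarray
    efficiencies_D_pct: np.ndarray
    E_D_median: float
    n_DA: int
    n_D: int
    p_value: float
    positive: bool
    summary_DA: BoxWhiskerSummary | None = None
    summary_D: BoxWhiskerSummary | None = None
    measurements: list[FretMeasurement] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def mean_DA(self) -> float:
        return float(np.mean(self.efficiencies_DA_pct))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "pair_name": self.pair_name,
            "n_DA": self.n_DA, "n_D": self.n_D,
            "E_D_median": self.E_D_median,
            "mean_efficiency_DA_pct": self.mean_DA,
            "mean_efficiency_D_pct": float(np.mean(self.efficiencies_D_pct)),
            "p_value": self.p_value, "positive": self.positive,
            "summary_DA": self.summary_DA.to_dict() if self.summary_DA else None,
            "summary_D": self.summary_D.to_dict() if self.summary_D else None,
            "flags": self.flags,
        }


def detect_spots(image: np.ndarray, min_separation_px: int = 5,
                 threshold_sd: float = 5.0,
                 half_width_px: int = DEFAULT_ROI_HALF_WIDTH) -> list[SpotROI]:
    """Detect diffraction-limited spots as band-pass local maxima.

    The image is band-pass filtered (difference of Gaussians, sigmas 1 and
    3 px), thresholded at the background median plus ``threshold_sd`` robust
    standard deviations (1.4826 * MAD), and non-maximum-suppressed at
    ``min_separation_px``.  Peaks too close to the border for a full
    measurement box are dropped.  Returns ROIs sorted by descending raw
    intensity; a blank image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D intensity image")
    bandpass = (ndimage.gaussian_filter(img, 1.0)
                - ndimage.gaussian_filter(img, 3.0))
    med = np.median(bandpass)
    mad = np.median(np.abs(bandpass - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        # noiseless images: the MAD degenerates, fall back to the plain SD
        robust_sd = float(bandpass.std())
    if robust_sd == 0:  # constant image: no texture, no spots
        return []
    thresh = med + threshold_sd * robust_sd
    peaks = peak_local_max(bandpass, min_distance=min_separation_px,
                           threshold_abs=thresh, exclude_border=False)
    rois = []
    for r, c in peaks:
        if (r - half_width_px < 0 or c - half_width_px < 0
                or r + half_width_px >= img.shape[0]
                or c + half_width_px >= img.shape[1]):
            logger.debug("dropping border peak at (%d, %d)", r, c)
            continue
        roi = SpotROI(center_px=(int(r), int(c)), half_width_px=half_width_px)
        roi.mean_intensity = measure_roi_mean(img, roi)
        rois.append(roi)
    rois.sort(key=lambda s: s.mean_intensity, reverse=True)
    return rois


def measure_roi_mean(image: np.ndarray, roi: SpotROI,
                     cell_id: str | None = None) -> float:
    """Arithmetic mean of the (2h+1) x (2h+1) box around the ROI center."""
    img = np.asarray(image, dtype=float)
    r, c = roi.center_px
    h = roi.half_width_px
    if r - h < 0 or c - h < 0 or r + h >= img.shape[0] or c + h >= img.shape[1]:
        who = f" (cell {cell_id})" if cell_id else ""
        raise ValueError(
            f"ROI box at {roi.center_px} half-width {h} falls outside the "
            f"{img.shape} image{who}")
    return float(img[r - h:r + h + 1, c - h:c + h + 1].mean())


def background_correct(FL: float, FL_bg: float) -> float:
    """Background-corrected intensity FL_cor = FL - FL_bg."""
    cor = FL - FL_bg
    if cor < 0:
        logger.warning("negative background-corrected intensity %.3f "
                       "(FL=%.3f, FL_bg=%.3f)", cor, FL, FL_bg)
    return cor


def percent_increase(FL_cor_pre: float, FL_cor_post: float) -> float:
    """Percentage increase of corrected donor signal after the bleach."""
    if FL_cor_pre <= 0:
        raise ValueError(
            f"corrected pre-bleach intensity must be positive, got {FL_cor_pre}")
    return 100.0 * (FL_cor_post - FL_cor_pre) / FL_cor_pre


def normalize_to_donor_median(E_DA, E_D, mode: str = "subtract"
                              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize efficiency values to the donor-only median.

    ``subtract`` (default) removes the donor-only median from every value,
    making the normalized donor-only median exactly 0.  ``divide`` is also
    available but is unstable when the donor-only median is near 0.
    """
    E_DA = np.asarray(E_DA, dtype=float)
    E_D = np.asarray(E_D, dtype=float)
    if E_D.size == 0:
        raise ValueError("donor-only control is empty; cannot normalize")
    med = float(np.median(E_D))
    if mode == "subtract":
        return E_DA - med, E_D - med, med
    if mode == "divide":
        if med == 0:
            raise ValueError("donor-only median is 0; division undefined")
        return E_DA / med, E_D / med, med
    raise ValueError(f"unknown normalization mode {mode!r}")


def classify_fret_pair(normalized_DA, normalized_D, alpha: float = 0.01,
                       equal_variance: bool = True,
                       pair_name: str = "pair",
                       E_D_median: float = 0.0) -> FretPairResult:
    """Call a pair FRET-positive from its normalized efficiency distributions.

    Positive requires both a two-tailed Student t-test p-value below
    ``alpha`` and a donor+acceptor mean above the donor-only mean (donor
    de-quenching must be an *increase*).  Too-small groups yield a negative
    result with a flag rather than an exception.
    """
    da = np.asarray(normalized_DA, dtype=float)
    d = np.asarray(normalized_D, dtype=float)
    flags: list[str] = []
    if da.size < 3 or d.size < 3:
        flags.append(f"insufficient sample size (n_DA={da.size}, n_D={d.size})")
        p_value = 1.0
        positive = False
    else:
        p_value = students_t_two_tailed(da, d, equal_variance=equal_variance)
        positive = bool(p_value < alpha and da.mean() > d.mean())
    return FretPairResult(
        pair_name=pair_name,
        efficiencies_DA_pct=da, efficiencies_D_pct=d,
        E_D_median=E_D_median, n_DA=int(da.size), n_D=int(d.size),
        p_value=p_value, positive=positive,
        summary_DA=box_whisker_summary(da) if da.size >= 4 else None,
        summary_D=box_whisker_summary(d) if d.size >= 4 else None,
        flags=flags,
    )


def _background_level(bg_cells, page: str, half_width: int) -> float:
    """Mean of cytoplasmic ROI means over untagged cells for one phase."""
    means = []
    for cell in bg_cells:
        img = cell.images[page]
        nrow, ncol = img.shape
        # fixed sampling positions away from borders; untagged cells carry
        # no spots, so any cytoplasmic region is background
        for fr, fc in ((0.25, 0.25), (0.25, 0.75), (0.5, 0.5),
                       (0.75, 0.25), (0.75, 0.75)):
            roi = SpotROI(center_px=(int(fr * nrow), int(fc * ncol)),
                          half_width_px=half_width)
            means.append(measure_roi_mean(img, roi, cell.cell_id))
    return float(np.mean(means))


def quantify_image_set(image_set, roi_half_width: int = DEFAULT_ROI_HALF_WIDTH,
                       min_separation_px: int = 5, threshold_sd: float = 5.0,
                       alpha: float = 0.01, equal_variance: bool = True,
                       normalization: str = "subtract",
                       pair_name: str | None = None) -> FretPairResult:
    """Run the full quantification on a pre-/post-bleach image set.

    For every donor+acceptor (DA) and donor-only (D) cell, the brightest
    spot is detected on the pre-bleach donor image and the same ROI is
    measured pre and post bleach; the per-phase background is the mean of
    cytoplasmic ROI means over the untagged (bg) cells.  Per-cell
    percentage increases are pooled, normalized to the donor-only median
    and tested for a positive FRET call.
    """
    classes = {c.sample_class for c in image_set.cells}
    for needed in ("DA", "D", "bg"):
        if needed not in classes:
            if needed == "D":
                raise ValueError("donor-only sample required: image set has "
                                 "no 'D' cells")
            raise ValueError(
                f"image set is missing the {needed!r} sample class")

    bg_cells = image_set.by_class("bg")
    bg_pre = _background_level(bg_cells, "donor_pre", roi_half_width)
    bg_post = _background_level(bg_cells, "donor_post", roi_half_width)

    measurements: list[FretMeasurement] = []
    e_by_class: dict[str, list[float]] = {"DA": [], "D": []}
    for cell in image_set.cells:
        if cell.sample_class == "bg":
            continue
        donor_pre = cell.images["donor_pre"]
        spots = detect_spots(donor_pre, min_separation_px=min_separation_px,
                             threshold_sd=threshold_sd,
                             half_width_px=roi_half_width)
        if not spots:
            logger.warning("cell %s excluded: no spot detected", cell.cell_id)
            continue
        roi = spots[0]  # brightest
        m = FretMeasurement(
            cell_id=cell.cell_id, sample_class=cell.sample_class,
            FL_pre=measure_roi_mean(donor_pre, roi, cell.cell_id),
            FL_post=measure_roi_mean(cell.images["donor_post"], roi,
                                     cell.cell_id),
            FL_bg_pre=bg_pre, FL_bg_post=bg_post,
        )
        measurements.append(m)
        if m.E_pct is not None:
            e_by_class[m.sample_class].append(m.E_pct)

    norm_da, norm_d, med = normalize_to_donor_median(
        e_by_class["DA"], e_by_class["D"], mode=normalization)
    result = classify_fret_pair(
        norm_da, norm_d, alpha=alpha, equal_variance=equal_variance,
        pair_name=pair_name or "pair", E_D_median=med)
    result.measurements = measurements
    return result


def quantify_table(table, alpha: float = 0.01, equal_variance: bool = True,
                   normalization: str = "subtract",
                   pair_name: str | None = None) -> FretPairResult:
    """Quantify a pre-measured intensity table.

    ``table`` is a DataFrame with columns ``cell_id, class, FL_pre, FL_post``
    and class labels in {DA, D, bg}; bg rows supply the per-phase background
    as the mean of their FL values.
    """
    required = {"cell_id", "class", "FL_pre", "FL_post"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table is missing columns {sorted(missing)}")
    bad = set(table["class"]) - {"DA", "D", "bg"}
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}; "
                         f"allowed values: ['DA', 'D', 'bg']")
    bg = table[table["class"] == "bg"]
    if bg.empty:
        raise ValueError("image set is missing the 'bg' sample class")
    if (table["class"] == "D").sum() == 0:
        raise ValueError("donor-only sample required: table has no 'D' rows")
    bg_pre = float(bg["FL_pre"].mean())
    bg_post = float(bg["FL_post"].mean())
    measurements = []
    e_by_class: dict[str, list[float]] = {"DA": [], "D": []}
    for _, row in table[table["class"] != "bg"].iterrows():
        m = FretMeasurement(
            cell_id=str(row["cell_id"]), sample_class=str(row["class"]),
            FL_pre=float(row["FL_pre"]), FL_post=float(row["FL_post"]),
            FL_bg_pre=bg_pre, FL_bg_post=bg_post)
        measurements.append(m)
        if m.E_pct is not None:
            e_by_class[m.sample_class].append(m.E_pct)
    norm_da, norm_d, med = normalize_to_donor_median(
        e_by_class["DA"], e_by_class["D"], mode=normalization)
    result = classify_fret_pair(
        norm_da, norm_d, alpha=alpha, equal_variance=equal_variance,
        pair_name=pair_name or "pair", E_D_median=med)
    result.measurements = measurements
    return result
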