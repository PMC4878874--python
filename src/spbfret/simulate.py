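"""Synthetic fluorescence-microscopy data with known ground truth.

This module generates the four kinds of synthetic data the analysis stages
consume:

* two-channel pre-/post-bleach image sets for acceptor-photobleaching FRET
  (donor+acceptor, donor-only and untagged sample classes),
* single-spot FRAP intensity traces with exponential recovery,
* spindle-length time-lapse traces with anaphase onset and breakdown events,
* paired spindle-pole-body (SPB) intensity tables with a configured
  asymmetry ratio.

The photophysics of the FRET simulator: a donor whose partner acceptor is
functional loses the quench factor ``q`` of its emission to energy transfer.
With pairing fraction ``p`` before the bleach and a bleach that destroys the
fraction ``beta`` of acceptors, the expected donor intensity is proportional
to ``1 - q*p`` before and ``1 - q*p*(1 - beta)`` after the bleach, so the
noiseless percentage increase is ``100 * q*p*beta / (1 - q*p)``; with
``p = beta = 1`` and ``q = e/(100+e)`` this equals the configured apparent
efficiency ``e`` exactly.

Pixel formation: expected photons (cytoplasmic background + PSF-integrated
spot) -> Poisson draw -> + camera offset + Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .config import ConfigError, FrapSimConfig, SimConfig, SpindleSimConfig
from .frap import FrapTrace
from .stats import SpindleTrace

# multi-page TIFF page order: the acquisition sequence of one bleach cycle
PAGE_ORDER = ("acceptor_pre", "donor_pre", "acceptor_post", "donor_post")

SAMPLE_CLASSES = ("DA", "D", "bg")


@dataclass
class SimulatedCell:
    """One simulated cell: four image pages plus its ground truth."""

    cell_id: str
    sample_class: str  # "DA" | "D" | "bg"
    images: dict[str, np.ndarray]
    true_center: tuple[float, float] | None  # (row, col), None for bg cells
    true_efficiency_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValueError(
                f"unknown sample class {self.sample_class!r}; "
                f"allowed: {SAMPLE_CLASSES}")


@dataclass
class FretImageSet:
    """A full synthetic FRET experiment: cells of all three sample classes."""

    cells: list[SimulatedCell]
    config: SimConfig

    def by_class(self, sample_class: str) -> list[SimulatedCell]:
        return [c for c in self.cells if c.sample_class == sample_class]


def _gaussian_spot(shape: tuple[int, int], center: tuple[float, float],
                   amplitude: float, sigma: float) -> np.ndarray:
    """Expected photons per pixel for a PSF-blurred point source.

    The Gaussian is integrated over each pixel area (separable difference of
    normal CDFs), so ``amplitude`` is the total expected photon count of the
    spot, independent of sigma.
    """
    nrow, ncol = shape
    r0, c0 = center
    rows = np.arange(nrow)
    cols = np.arange(ncol)
    fr = ndtr((rows + 0.5 - r0) / sigma) - ndtr((rows - 0.5 - r0) / sigma)
    fc = ndtr((cols + 0.5 - c0) / sigma) - ndtr((cols - 0.5 - c0) / sigma)
    return amplitude * np.outer(fr, fc)


def _render(expected_photons: np.ndarray, cfg: SimConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Photon expectation -> camera frame (shot noise, offset, read noise)."""
    if cfg.shot_noise:
        photons = rng.poisson(expected_photons).astype(float)
    else:
        photons = expected_photons.copy()
    frame = photons + cfg.camera_offset
    if cfg.read_noise_sd > 0:
        frame = frame + rng.normal(0.0, cfg.read_noise_sd, frame.shape)
    return frame


def simulate_fret_image_set(config: SimConfig) -> FretImageSet:
    """Simulate an acceptor-photobleaching FRET experiment.

    Returns a :class:`FretImageSet` whose cells carry four image pages each
    (acceptor pre, donor pre, acceptor post, donor post — the acquisition
    order of one bleach cycle) plus ground-truth spot centers and class
    labels.

    DA cells have donor emission quenched by ``q * pairing_fraction`` before
    the bleach and ``q * pairing_fraction * (1 - bleach_efficiency)`` after
    it; D cells carry an unquenched donor and no acceptor; bg cells are
    background only.
    """
    cfg = config  # validated on construction
    rng = np.random.default_rng(cfg.seed)
    q = cfg.quench_factor
    p = cfg.pairing_fraction
    beta = cfg.bleach_efficiency
    a = cfg.acquisition_bleach_per_frame
    shape = cfg.image_shape_px
    margin = math.ceil(4 * cfg.psf_sigma_px) + 3

    cells: list[SimulatedCell] = []

    def spot_center() -> tuple[float, float]:
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        return (r, c)

    def make_cell(idx: int, sample_class: str) -> SimulatedCell:
        bg = np.full(shape, cfg.cyto_background, dtype=float)
        images: dict[str, np.ndarray] = {}
        if sample_class == "bg":
            center = None
            for page in PAGE_ORDER:
                images[page] = _render(bg, cfg, rng)
            true_e = 0.0
        else:
            center = spot_center()
            has_acceptor = sample_class == "DA"
            quench_pre = q * p if has_acceptor else 0.0
            quench_post = q * p * (1.0 - beta) if has_acceptor else 0.0
            donor_pre = bg + _gaussian_spot(
                shape, center, cfg.donor_amplitude * (1.0 - quench_pre),
                cfg.psf_sigma_px)
            donor_post = bg + _gaussian_spot(
                shape, center,
                cfg.donor_amplitude * (1.0 - quench_post) * (1.0 - a),
                cfg.psf_sigma_px)
            acc_amp = cfg.acceptor_amplitude if has_acceptor else 0.0
            acceptor_pre = bg + _gaussian_spot(
                shape, center, acc_amp, cfg.psf_sigma_px)
            acceptor_post = bg + _gaussian_spot(
                shape, center, acc_amp * (1.0 - beta), cfg.psf_sigma_px)
            for page, expected in zip(
                    PAGE_ORDER,
                    (acceptor_pre, donor_pre, acceptor_post, donor_post)):
                images[page] = _render(expected, cfg, rng)
            # noiseless percentage increase this cell was built to show
            true_e = 100.0 * ((1.0 - quench_post) * (1.0 - a)
                              / (1.0 - quench_pre) - 1.0)
        return SimulatedCell(
            cell_id=f"{sample_class}_{idx:04d}",
            sample_class=sample_class,
            images=images,
            true_center=center,
            true_efficiency_pct=true_e,
        )

    for i in range(cfg.n_cells_DA):
        cells.append(make_cell(i, "DA"))
    for i in range(cfg.n_cells_D):
        cells.append(make_cell(i, "D"))
    for i in range(cfg.n_cells_bg):
        cells.append(make_cell(i, "bg"))
    return FretImageSet(cells=cells, config=cfg)


def simulate_frap_trace(config: FrapSimConfig) -> FrapTrace:
    """Simulate one FRAP trace: pre-bleach plateau, bleach step, recovery.

    The post-bleach intensity follows
    ``I(t) = I_bleach + (I_plateau - I_bleach) * (1 - exp(-k t))`` with
    ``t`` counted from the first post-bleach frame; the recovery plateau is
    ``1 - immobile_fraction * bleach_depth`` of the pre-bleach level.
    Ground-truth rate and half-time travel with the trace.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pre, n_post = cfg.pre_bleach_frames, cfg.post_bleach_frames
    dt = cfg.frame_interval_s
    n = n_pre + n_post
    time_s = np.arange(n) * dt
    intensity = np.empty(n, dtype=float)
    intensity[:n_pre] = 1.0
    i_bleach = 1.0 - cfg.bleach_depth
    plateau = 1.0 - cfg.immobile_fraction * cfg.bleach_depth
    t_post = np.arange(n_post) * dt
    k = cfg.off_rate_per_s
    recovery = 1.0 - np.exp(-k * t_post) if k > 0 else np.zeros(n_post)
    intensity[n_pre:] = i_bleach + (plateau - i_bleach) * recovery
    intensity *= cfg.intensity_scale
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, cfg.noise_sd * cfg.intensity_scale, n)
    return FrapTrace(
        time_s=time_s,
        intensity=intensity,
        bleach_index=n_pre,
        truth={
            "off_rate_per_s": k,
            "t_half_s": cfg.t_half_s,
            "immobile_fraction": cfg.immobile_fraction,
            "bleach_depth": cfg.bleach_depth,
        },
    )


def simulate_frap_traces(config: FrapSimConfig, n_traces: int) -> list[FrapTrace]:
    """Simulate ``n_traces`` independent FRAP traces from one configuration."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_traces)
    return [simulate_frap_trace(config.replace(seed=int(s) % (2**31)))
            for s in seeds]


def simulate_spindle_traces(config: SpindleSimConfig) -> list[SpindleTrace]:
    """Simulate spindle-length traces with known anaphase onset/breakdown.

    Each trace: metaphase plateau at the pre-anaphase length, linear rapid
    elongation from the drawn onset time, anaphase plateau, abrupt collapse
    at the drawn breakdown time.  Breakdown always falls strictly after
    onset (durations are redrawn if a draw comes out non-positive).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    traces: list[SpindleTrace] = []
    for i in range(cfg.n_cells):
        onset = rng.normal(cfg.onset_time_mean_min, cfg.onset_time_sd_min)
        onset = max(onset, 2.0 * cfg.sampling_interval_min)
        duration = rng.normal(cfg.anaphase_duration_mean_min,
                              cfg.anaphase_duration_sd_min)
        while duration <= cfg.sampling_interval_min:
            duration = rng.normal(cfg.anaphase_duration_mean_min,
                                  cfg.anaphase_duration_sd_min)
        breakdown = onset + duration
        t_end = breakdown + 5.0
        time = np.arange(0.0, t_end + cfg.sampling_interval_min,
                         cfg.sampling_interval_min)
        length = np.full(time.shape, cfg.pre_anaphase_length_um)
        elong = (time > onset) & (time < breakdown)
        length[elong] = np.minimum(
            cfg.pre_anaphase_length_um
            + cfg.elongation_rate_um_per_min * (time[elong] - onset),
            cfg.plateau_length_um)
        length[time >= breakdown] = cfg.collapsed_length_um
        if cfg.length_noise_sd_um > 0:
            length = length + rng.normal(0.0, cfg.length_noise_sd_um,
                                         length.shape)
        traces.append(SpindleTrace(
            time_min=time,
            length_um=length,
            truth={"onset_min": onset, "breakdown_min": breakdown,
                   "duration_min": duration},
        ))
    return traces


def simulate_spb_intensity_table(n_cells: int, asymmetry_ratio: float,
                                 noise_cv: float, seed: int = 0):
    """Simulate per-cell intensities of the two spindle pole bodies.

    The brighter pole's mean intensity is ``asymmetry_ratio`` times the
    dimmer pole's; both carry multiplicative lognormal noise with the given
    coefficient of variation.  Returns a pandas DataFrame with columns
    ``cell_id, intensity_a, intensity_b, true_bright`` where ``true_bright``
    names the ground-truth brighter pole ("a" or "b"); the bright pole is
    assigned to a or b at random so downstream classification is non-trivial.
    """
    import pandas as pd

    if asymmetry_ratio < 1:
        raise ConfigError(
            f"asymmetry_ratio must be >= 1, got {asymmetry_ratio!r}")
    if noise_cv < 0:
        raise ConfigError(f"noise_cv must be >= 0, got {noise_cv!r}")
    rng = np.random.default_rng(seed)
    base = 100.0
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    def draw(mean: float) -> float:
        if sigma == 0:
            return mean
        # lognormal with E[X] = mean and CV = noise_cv
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    rows = []
    for i in range(n_cells):
        bright = draw(base * asymmetry_ratio)
        dim = draw(base)
        if rng.random() < 0.5:
            rows.append((f"cell_{i:04d}", bright, dim, "a"))
        else:
            rows.append((f"cell_{i:04d}", dim, bright, "b"))
    return pd.DataFrame(
        rows, columns=["cell_id", "intensity_a", "intensity_b", "true_bright"])
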