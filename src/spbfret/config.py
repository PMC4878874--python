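"""Simulation configurations with ground-truth parameterization.

Every configuration is an immutable-ish dataclass that validates its physics
on construction: fractions live in [0, 1], amplitudes and counts are strictly
positive, and an identical (config, seed) pair always reproduces the same
synthetic data bit for bit.

The FRET ground truth is stated as the *apparent* efficiency ``e`` — the
percentage increase of background-corrected donor signal after acceptor
photobleaching — because that is the quantity the quantification pipeline
reports.  Internally it maps to a donor quench factor ``q = e / (100 + e)``,
chosen so that with complete bleaching and full pairing the pipeline returns
exactly ``e``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a simulation configuration is not physically valid."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ConfigError(f"{name} must be strictly positive, got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if not value >= 0:
        raise ConfigError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameterization of a synthetic acceptor-photobleaching FRET experiment.

    Parameters
    ----------
    apparent_efficiency_pct
        Target percentage donor de-quenching for donor+acceptor (DA) cells.
        This is the ground truth the quantification pipeline should recover.
    n_cells_DA, n_cells_D, n_cells_bg
        Number of simulated cells per sample class: donor+acceptor,
        donor-only, and untagged background cells.
    donor_amplitude, acceptor_amplitude
        Expected total photons collected from one unquenched spot per
        exposure (integrated over the point-spread function).
    bleach_efficiency
        Fraction of acceptor fluorophores destroyed by the bleach pulse.
    pairing_fraction
        Fraction of donor molecules within Förster distance of a functional
        acceptor before the bleach.
    psf_sigma_px
        Standard deviation of the isotropic Gaussian point-spread function,
        in pixels.
    cyto_background
        Expected cytoplasmic background photons per pixel per exposure.
    camera_offset
        Constant camera offset added to every pixel, in counts.
    read_noise_sd
        Standard deviation of additive Gaussian read noise, in counts.
    acquisition_bleach_per_frame
        Fractional donor signal lost per donor exposure (photobleaching by
        the imaging light itself).
    shot_noise
        If False, pixel values are the noiseless expectations (used by the
        closed-form test suites).
    image_shape_px, pixel_size_um
        Per-cell image geometry.
    seed
        Base seed for the random stream.
    """

    apparent_efficiency_pct: float = 14.0
    n_cells_DA: int = 40
    n_cells_D: int = 40
    n_cells_bg: int = 20
    donor_amplitude: float = 5000.0
    acceptor_amplitude: float = 5000.0
    bleach_efficiency: float = 1.0
    pairing_fraction: float = 1.0
    psf_sigma_px: float = 1.3
    cyto_background: float = 50.0
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    acquisition_bleach_per_frame: float = 0.0
    shot_noise: bool = True
    image_shape_px: tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.1067
    seed: int = 0

    def __post_init__(self) -> None:
        _check_nonnegative("apparent_efficiency_pct", self.apparent_efficiency_pct)
        for name in ("n_cells_DA", "n_cells_D", "n_cells_bg"):
            _check_positive(name, getattr(self, name))
        for name in ("donor_amplitude", "acceptor_amplitude", "psf_sigma_px"):
            _check_positive(name, getattr(self, name))
        for name in ("bleach_efficiency", "pairing_fraction",
                     "acquisition_bleach_per_frame"):
            _check_fraction(name, getattr(self, name))
        for name in ("cyto_background", "read_noise_sd", "camera_offset"):
            _check_nonnegative(name, getattr(self, name))
        nrow, ncol = self.image_shape_px
        # a spot needs its PSF plus a measurement box to fit inside the frame
        margin = 2 * (math.ceil(4 * self.psf_sigma_px) + 3)
        if nrow < margin or ncol < margin:
            raise ConfigError(
                f"image_shape_px {self.image_shape_px} too small to contain "
                f"a spot plus ROI margin (needs at least {margin} px per axis)"
            )

    @property
    def quench_factor(self) -> float:
        """Donor quench factor q = e / (100 + e)."""
        e = self.apparent_efficiency_pct
        return e / (100.0 + e)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def noiseless(self) -> "SimConfig":
        """Copy of this config with all noise sources switched off."""
        return self.replace(shot_noise=False, read_noise_sd=0.0)


@dataclass(frozen=True)
class FrapSimConfig:
    """Parameterization of a synthetic FRAP experiment on one spot.

    Recovery follows I(t) = I_bleach + (I_plateau - I_bleach) * (1 - exp(-k t))
    with t measured from the first post-bleach frame.  The recovery plateau is
    depressed below the pre-bleach level by ``immobile_fraction`` of the
    bleached signal; the ground-truth half-recovery time is ln(2)/k.
    """

    off_rate_per_s: float = math.log(2) / 11.0
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.8
    pre_bleach_frames: int = 10
    post_bleach_frames: int = 90
    frame_interval_s: float = 1.0
    intensity_scale: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_nonnegative("off_rate_per_s", self.off_rate_per_s)
        _check_fraction("immobile_fraction", self.immobile_fraction)
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ConfigError(
                f"bleach_depth must lie in (0, 1], got {self.bleach_depth!r}")
        _check_positive("pre_bleach_frames", self.pre_bleach_frames)
        if self.pre_bleach_frames < 3:
            raise ConfigError("need at least 3 pre-bleach frames")
        _check_positive("post_bleach_frames", self.post_bleach_frames)
        _check_positive("frame_interval_s", self.frame_interval_s)
        _check_positive("intensity_scale", self.intensity_scale)
        _check_nonnegative("noise_sd", self.noise_sd)

    @property
    def t_half_s(self) -> float:
        """Ground-truth half-recovery time ln(2)/k (inf when k = 0)."""
        if self.off_rate_per_s == 0:
            return math.inf
        return math.log(2) / self.off_rate_per_s

    def replace(self, **kwargs) -> "FrapSimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SpindleSimConfig:
    """Parameterization of synthetic spindle-length time-lapse traces.

    Each cell follows a biphasic trajectory: a short metaphase plateau, linear
    rapid elongation starting at a drawn onset time, an anaphase plateau, and
    an abrupt collapse at the drawn breakdown time (onset + duration).
    """

    n_cells: int = 30
    onset_time_mean_min: float = 10.0
    onset_time_sd_min: float = 2.0
    anaphase_duration_mean_min: float = 23.0
    anaphase_duration_sd_min: float = 4.0
    pre_anaphase_length_um: float = 1.5
    plateau_length_um: float = 8.0
    elongation_rate_um_per_min: float = 1.0
    collapsed_length_um: float = 0.8
    length_noise_sd_um: float = 0.05
    sampling_interval_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("n_cells", self.n_cells)
        _check_positive("onset_time_mean_min", self.onset_time_mean_min)
        _check_nonnegative("onset_time_sd_min", self.onset_time_sd_min)
        _check_positive("anaphase_duration_mean_min",
                        self.anaphase_duration_mean_min)
        _check_nonnegative("anaphase_duration_sd_min",
                           self.anaphase_duration_sd_min)
        _check_positive("pre_anaphase_length_um", self.pre_anaphase_length_um)
        _check_positive("plateau_length_um", self.plateau_length_um)
        _check_positive("elongation_rate_um_per_min",
                        self.elongation_rate_um_per_min)
        _check_positive("sampling_interval_min", self.sampling_interval_min)
        _check_nonnegative("length_noise_sd_um", self.length_noise_sd_um)
        if self.plateau_length_um <= self.pre_anaphase_length_um:
            raise ConfigError("plateau length must exceed pre-anaphase length")

    def replace(self, **kwargs) -> "SpindleSimConfig":
        return dataclasses.replace(self, **kwargs)
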