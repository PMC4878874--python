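# Methods

## Acceptor-photobleaching FRET model

The simulator and the quantification pipeline share one photophysical
model.  A donor fluorophore whose partner acceptor is functional and within
Förster distance loses a fraction *q* (the quench factor) of its emission
to energy transfer.  With a fraction *p* of donors paired before the bleach
and a bleach pulse destroying a fraction *β* of acceptors, the expected
donor intensity at the spot is proportional to

    pre-bleach:   1 − q·p
    post-bleach:  (1 − q·p·(1−β)) · (1 − a)

where *a* is the fractional donor loss per donor exposure from the imaging
light itself.  The noiseless percentage increase (Eq. 2 of the README) is
therefore

    E% = 100 · q·p·β / (1 − q·p)        (for a = 0).

Ground truth is parameterized as the *apparent* efficiency *e* — the E%
the pipeline should report — rather than a molecular transfer efficiency,
because the apparent percentage increase is the quantity the measurement
chain actually produces.  The mapping `q = e/(100+e)` is chosen so that
with complete bleaching (β = 1) and full pairing (p = 1) the pipeline
returns exactly *e*.  This identity is exercised at 1e−9 tolerance in the
noiseless property suite.

Sanity check of the partial-bleach algebra: for e = 26 (q = 26/126 ≈
0.2063) and β = 0.5, E% = 100·q·0.5/(1−q) = 13.0 — exactly half of the
full-bleach 26%, as it must be since E% is linear in β.

### Image formation

Each simulated cell is a single-plane 2D frame (the donor emission of the
modeled experiment is recorded from one plane).  Spots are isotropic
Gaussians integrated over pixel areas (separable normal-CDF differences),
so the amplitude parameter is the expected *total* photon count of the
spot, independent of the PSF width.  Pixel values are formed as

    expected photons (cytoplasmic background + spot)
      → Poisson draw → + camera offset → + Gaussian read noise.

EM-gain excess noise is not modeled; at the simulated photon budgets it
would inflate all variances by a common factor without changing any of the
ratios the pipeline measures.  There is no drift between pre- and
post-bleach frames, so a single ROI per cell is exact; real data would
need registration first.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| donor_amplitude | 5000 photons | bright SPB spot on a 60× system; gives per-cell E% noise of ~3%, comparable to published per-cell spreads |
| psf_sigma_px | 1.3 px | diffraction-limited spot at ~107 nm pixels |
| cyto_background | 50 photons/px | visible but spot-dominated background |
| camera_offset, read_noise_sd | 100, 2 counts | typical CCD bias/read noise |
| bleach_efficiency β | 1.0 | bleach completeness after the pulse is not known; exposed as a parameter, complete bleaching assumed by default |
| pairing_fraction p | 1.0 | tandem-fusion geometry; lower for heterologous pairs |
| acquisition_bleach_per_frame | 0 | donor acquisition bleaching is not reported for the modeled experiments; the donor-only median normalization exists precisely to absorb it when nonzero, which the donor-only null test verifies |
| n_cells (DA/D/bg) | 40/40/20 | sample sizes of the recovery studies |

### Quantification pipeline choices

* **ROI**: 5×5 px box centered on the detected intensity maximum.  For a
  1.3 px PSF this captures ~87% of spot photons and is close to the
  SNR-optimal box size; the box half-width is configurable.
* **Spot detection** is difference-of-Gaussians band-pass (σ 1 and 3 px)
  with a robust threshold (median + k·1.4826·MAD) and non-maximum
  suppression.  On noiseless images the MAD degenerates to 0 and the plain
  standard deviation is used instead.  Because the same ROI is measured
  pre and post bleach, the captured-fraction factor cancels in the ratio,
  so sub-pixel center error does not bias E%.
* **Background** is taken per phase (pre/post) as the mean of five
  fixed-position cytoplasmic ROI means per untagged cell, pooled over the
  untagged sample.  Pooling per experiment (rather than per image) keeps
  the background estimate's noise negligible against per-cell shot noise.
* **Normalization** to the donor-only control is implemented as
  *subtraction* of the median E%(D).  Division is also available, but a
  donor-only median near zero makes it unstable, and subtraction makes the
  normalized donor-only median exactly zero (to one ulp when the group
  size is even and the median averages two values).
* **Call rule**: equal-variance two-tailed Student t-test (Welch behind a
  flag), positive iff p < 0.01 *and* the DA mean exceeds the D mean —
  de-quenching must be an increase.
* Cells whose corrected pre-bleach intensity is ≤ 0 are excluded and
  logged with the reason, never imputed; the per-cell CSV retains them.

## FRAP model and fitting

Traces are a pre-bleach plateau, an instantaneous drop by the bleach
depth, and exponential recovery to a plateau depressed by the immobile
fraction.  Fitting normalizes to the pre-bleach mean (optionally dividing
frame-wise by an unbleached reference trace to cancel acquisition
bleaching) and least-squares fits `c + a·(1 − exp(−k t))` on the
post-bleach frames, with t = 0 at the first post-bleach frame.  Because
single-exponential fits are initialization-sensitive, the fit is
multi-started over k ∈ {0.01, 0.05, 0.1, 0.5, 1} s⁻¹ and the lowest
residual is kept.  A failed optimizer returns `converged=False`; an
effectively flat recovery (k < 1e−3 s⁻¹, or vanishing amplitude, where k
is unidentifiable) reports t½ = ∞ rather than raising — "no recovery" is a
scientific outcome, not an error.

Both per-trace fitting and fitting of the averaged recovery curve are
provided; the averaged-curve fit is the default headline number because
averaging suppresses the right-skewed error of single-trace rate
estimates.  The fast-exchange fixture observes 90 s post-bleach (~8
half-times at t½ = 11 s); the slow-exchange fixture observes 240 s (~3.6
half-times at t½ = 66 s), the usual design point of covering at least
three half-times so the plateau is constrained.  Trace noise defaults to
SNR 10 (noise sd = 10% of the pre-bleach level).

## Spindle time-lapse scoring

Simulated trajectories: metaphase plateau 1.5 µm → linear elongation at
1 µm/min from a drawn onset time → anaphase plateau 8 µm → abrupt collapse
to 0.8 µm at the drawn breakdown time, plus 0.05 µm measurement noise,
sampled at 1 min.  The scorer detects onset as the first timepoint whose
centered 3-point elongation rate exceeds 0.5 µm/min and breakdown as the
first later timepoint below 0.5× the running maximum length.  Both events
are detected at the first sample at or after the true event time, so the
±½-sample biases cancel in the duration; durations are unbiased to within
one sampling interval.  Cells without a detected breakdown (arrested) or
onset are reported as censored with the reason, mirroring ">60 min"-style
reporting rather than being dropped silently.

## SPB intensity tables

Paired pole intensities are lognormal around a configured bright/dim mean
ratio (≥1), with the bright pole assigned to either slot at random so the
bright/dim classification is non-trivial.  Classification orders each pair
as (SPB1, SPB2) = (bright, dim); ties keep input order and set a flag.

## Statistics conventions

Quartiles use inclusive linear interpolation (the spreadsheet/plotting
default), fences at 1.5×IQR, whiskers at the extreme data values inside
the fences; every point outside is an outlier and is always *reported*
(display is the caller's choice).  Degenerate t-test inputs are resolved
explicitly (identical constant groups → p = 1; separated constant groups →
the p → 0 limit, flagged).  A constant response in the trend fit is
defined to have R² = 0.

## What the synthetic data does and does not show

The generator reproduces the *measurement physics* — quenching arithmetic,
shot/read noise, background, exponential exchange, biphasic elongation —
with hard ground truth, so passing tests demonstrate that the analysis
chain is correct and unbiased at realistic noise levels.  It does not
emulate cell morphology, spot drift or z-defocus, EM-gain noise,
biological cell-to-cell variability of the efficiency itself, or
diffusion-coupled FRAP; recovery on synthetic data therefore bounds
algorithmic error only, not the full experimental error of real images.
Parameter-recovery checks are statistical by nature: a mean over 40 cells
compared at two standard errors fails ~5% of random draws even for a
perfect estimator, which is the expected behavior of a frozen-seed
stochastic check, not a regression.

## Problem sizes

Default study sizes (40/40/20 cells on 64×64 px frames, 20 FRAP traces of
100 frames, 30 spindle traces) run the full acceptance battery in a few
seconds on one CPU; they are the sizes at which the recovery tolerances
above are calibrated.
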