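# spbfret

Quantification tools for fluorescence-microscopy experiments on
spindle-pole-body (SPB) proteins in budding yeast — acceptor-photobleaching
FRET, FRAP recovery kinetics, SPB intensity statistics and spindle
time-lapse scoring — together with a synthetic data generator that encodes
the photophysics the analyses assume, so every stage can be validated
against known ground truth.

## Who this is for

Groups measuring protein–protein proximity at diffraction-limited
structures (centrosomes, SPBs, kinetochores) with acceptor-photobleaching
FRET, and anyone who needs a tested, scriptable reimplementation of the
standard ImageJ-style workflow: ROI means, background subtraction,
percentage de-quenching, donor-only normalization and a significance call.

## The quantities computed

**FRET efficiency (donor de-quenching).** FRET quenches the donor; a laser
pulse that destroys the acceptor de-quenches it. With `FL` the mean donor
intensity in a small box around the SPB spot and `FL(bg)` a cytoplasmic
region of an untagged cell:

    FL_cor       = FL − FL(bg)                                   (1)
    E%           = 100 · (FL_cor_post − FL_cor_pre) / FL_cor_pre (2)
    efficiency%  = E% − median(E% of donor-only cells)           (3)

Donor-only (D) control cells carry the donor but no acceptor; subtracting
their median E% centers the null distribution at exactly 0.  A pair is
called FRET-positive when the donor+acceptor (DA) distribution is higher
than the D distribution with p < 0.01 (two-tailed Student t-test) and a
larger mean.

**FRAP recovery.** Post-bleach spot intensity is fitted with the
reaction-dominant single exponential `I(t) = c + a·(1 − exp(−k t))`; the
half-recovery time is `t½ = ln 2 / k` and the mobile fraction is the
recovered amplitude relative to the bleached depth.

**Time-lapse scoring.** Anaphase duration is the time between the onset of
rapid spindle elongation (sliding-window rate threshold) and spindle
breakdown (collapse below a fraction of the running plateau length).

**Descriptive statistics.** Box-whisker summaries with inclusive
linear-interpolation quartiles and the 1.5×IQR outlier fence, SPB1/SPB2
(bright/dim) classification, max-to-1 normalization and OLS trend R².

## Worked example

Simulate the tandem donor–acceptor fusion fixture (ground-truth apparent
efficiency 26%, 40 DA / 40 D / 20 untagged cells, Poisson + read noise) and
quantify it:

```
$ spbfret simulate --fixture tandem_bfa1 --seed 7 --out demo/images
$ spbfret quantify-fret --images demo/images --out demo/fret
mean normalized efficiency (DA): 26.11% (p=1.36e-56, positive=True)
```

The pipeline detects each cell's spot on the pre-bleach donor image,
measures the same 5×5 px box pre and post bleach, subtracts the untagged
background, computes the per-cell percentage increase (2), normalizes to
the donor-only median (3), and recovers the configured 26% within sampling
error; the t-test against the donor-only control is decisive.

FRAP and time-lapse stages run the same way:

```
$ spbfret simulate --fixture kar9_misaligned_frap --seed 7 --n-traces 20 \
      --out demo/frap
$ spbfret fit-frap --traces demo/frap/frap_traces.csv --out demo/fits
t_half = 12.08 s (average)

$ spbfret simulate --fixture spc72_aligned_spindle --seed 7 --out demo/sp
$ spbfret score-timelapse --traces demo/sp/spindle_traces.csv --out demo/scores
mean anaphase duration: 21.6 min over 30 cells
```

The FRAP fixture's configured half-time is 11 s and the spindle fixture's
configured mean duration is 23 min (sd 4); both estimates sit within the
sampling error of 20 traces / 30 cells.  `spbfret run-all --config run.yaml
--seed N --out DIR` chains all three stages from one YAML file and writes a
config echo for reproducible re-runs.

Everything is also available as a library:

```python
from spbfret import get_fixture, simulate_fret_image_set, quantify_image_set

result = quantify_image_set(simulate_fret_image_set(get_fixture("spc42_cnm67", seed=0)))
print(result.mean_DA, result.p_value, result.positive)
```

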