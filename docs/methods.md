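# Methods

## Forward model and what the generator emulates

The acquisition being modelled is a single-spin-echo sequence whose TR is
varied while TE stays fixed (11 ms).  Under saturation recovery the pixel
signal is `S(TR) = S0 (1 - exp(-TR R1))`; TE-weighting and proton density
are absorbed into S0.  This forward model was chosen so that the
three-parameter fit form `a + b exp(-c TR)` is exact with `a = S0`,
`b = -S0`, `c = R1` — the variable-TR single-spin-echo acquisition implies
saturation recovery, and no other recovery model reproduces the fit form
without approximation.

The generator renders, per subject, one image per scheduled repeat
(default 23 over 8 TRs, short TRs repeated more often), each equal to
coil-field x signal-model per pixel, rigidly translated by a sampled
jitter, with Rician noise (magnitude of a complex Gaussian perturbation).
Ground truth (R1 map, S0 map, coil field, per-image shifts) is emitted
alongside.  Defaults:

- **Noise** `sigma = 0.03` in S0 units: gives ROI SNR ~ 20 at the longest
  TR for S0 = 1 tissue.  Magnitude MRI noise is Rician, positively biased
  at low signal; the zero-signal mean is `sigma sqrt(pi/2)`, which the
  tests verify by Monte Carlo.
- **Jitter** rigid translation per image, `sd = 0.5 px`, to exercise the
  registration stages.  No rotation is simulated (and the registration
  estimates translation only).
- **Coil field** uniform, low-order polynomial, or Gaussian bump, strictly
  positive, slowly varying relative to the 3x3 smoothing support.
- **Cohort** group sizes 11 (NH) / 11 (NE) / 8 (NE+AO); per-group, per-ear
  R1 means (1/s): NH 0.236 unprotected / 0.249 protected, NE 0.301 / 0.228,
  NE+AO 0.240 / 0.234; between-subject SDs are the printed SEMs scaled by
  sqrt(n).  The generator treats these as absolute rates; a helper
  re-expresses tables as change from the NH protected-ear mean for display
  conventions that plot deltas.  Subject R1 values are drawn normally and
  redrawn in the (practically unreachable) nonpositive tail, since R1 is a
  rate.

What the generator does **not** emulate: k-space sampling, slice-profile
or B0 effects, anatomically realistic cochlear geometry, T2/TE modelling,
partial-volume structure, or day-to-day scanner drift.  Passing tests
therefore demonstrate correctness of the analysis chain under the stated
noise/field/motion model, not robustness to every artefact of real
scanners.

## R1 mapping chain

- **Registration**: subpixel phase correlation (translation only),
  upsampling factor 100.  Within a TR the reference is the first repeat;
  across TRs it is the longest-TR (highest-SNR) image.  Constant images
  carry no registration information and get an identity transform plus a
  warning flag.
- **Averaging**: arithmetic mean per TR, output sorted by ascending TR.
  Fewer than 4 distinct TRs is refused (the three-parameter fit would be
  under-determined); missing TR groups relative to an expected schedule
  warn and proceed.
- **Smoothing**: the 3x3 kernel is the binomial (1,2,1)x(1,2,1)/16
  (discrete Gaussian, sigma ~ 0.85 px), applied three times, `nearest`
  boundary handling so constants are preserved at the edge.  Three passes
  give an effective 7x7 support.
- **Normalization**: every non-reference TR image is divided by the
  smoothed 0.15 s image ("divided into" is read as others / reference,
  since the stated purpose is to cancel the coil profile common to all
  images).  Pixels where the smoothed reference falls below 1e-6 of its
  maximum are masked.  The reference TR does not rejoin the fit: exactly
  the seven normalized images are fitted.
- **Fit**: per-pixel nonlinear least squares. Initialization: `a0` = value
  at the longest TR; `c0` from a log-linear regression of `a0 - y` on TR
  over points where that difference is positive (fallback `1/median TR`);
  `b0 = -a0`.  Bounds `c` in (0, 100] 1/s; tolerance 1e-8; 200 iteration
  cap; a solver failure or a rate pinned at a bound is flagged
  non-converged (NaN parameters, never silent zeros).  `fit_t1_map` runs a
  batched Levenberg-Marquardt over all masked pixels (identical model,
  init and bounds); the per-pixel path is retained as the reference
  implementation and the two are held to agreement in the tests, alongside
  a brute-force profile oracle (dense c grid with linear a, b solves).

Division by the per-pixel smoothed reference is a TR-independent scaling,
so it cancels any strictly positive multiplicative field exactly and
cannot bias `c`; the acceptance checks verify noiseless end-to-end
recovery (max relative error < 1e-4) and per-pixel field invariance (< 1%).

## Group statistics

ROI-mean R1 per (subject, ear) feeds a treatment x ear two-way ANOVA.
Type II sums of squares are used because the design is unbalanced
(11/11/8) and the hypotheses of interest are main effects; the interaction
is still reported.  Post hoc contrasts among the three treatment groups
within one ear use Scheffé's procedure (`t^2/(k-1)` against `F(k-1,
df_resid)`, k = 3 groups, residual mean square from the two-way model).
Planned (unadjusted) contrasts are available via `method="planned"`; which
of the two generated the original figure p-values is not determinable, so
both paths are exposed and Scheffé — the procedure named for this
comparison — is the default.  Alpha is 0.05 and a boundary p = alpha
counts as significant.

The quench decision: `elevated` = NE above NH in the unprotected ear at
alpha; `quenched` = NE+AO below NE at alpha *and* NE+AO not different from
NH.  At the study conditions (printed means, SEM-implied spreads, n =
11/11/8) the joint probability of both flags is ~0.74 under Scheffé
contrasts and ~0.92 under planned contrasts; the high-variance
NE-protected cell (SD ~ 0.07 1/s) inflates the pooled residual MS and is
the main power cost.

HO-1 percent changes (`100 (signal - background)/background`, background
from a no-epithelium region) are analysed with a mixed-factor ANOVA:
fixed treatment + ear, a random intercept per rat, and separate residual
variances for the two ears, fitted by REML.  The implementation profiles
the left-ear residual variance analytically and optimizes the two
remaining variance ratios by Nelder-Mead (Sherman-Morrison block
inversion, so each evaluation is O(records)).  No installed package
exposes this ear-stratified residual structure, hence the direct
implementation; in balanced designs the treatment F-test provably
collapses to a one-way ANOVA on rat means, which the tests verify to
1e-6.  The treatment F uses between-rat denominator degrees of freedom
(n_rats - n_groups); least-squares means average over ears and pairwise
comparisons use the same denominator df.

## ABR

Simulated evoked waveforms are 15 ms at 24.4 kHz with the stimulus at
10 ms, a biphasic wave-1 deflection (peak 12.0 ms, trough 12.4 ms) whose
peak-to-trough amplitude is zero strictly below the true threshold and
grows linearly above it (1.0 uV at threshold + 0.04 uV/dB), and
band-limited Gaussian baseline noise (Gaussian-smoothed, 1.0 ms
correlation scale, ensemble-calibrated SD, default 0.15 uV for the
1024-trial average).  The noise is deliberately smoother than a typical
ABR passband: with the simple peak-to-trough presence criterion below, a
broadband noise floor would trigger constantly, and the generator's role
is to exercise the threshold logic with a controllable false-positive
rate (~0.3% at the default criterion), not to reproduce ABR spectra.

Wave-1 presence: peak-to-trough amplitude in the 11.6-12.6 ms window at
least `k = 3` times the pre-stimulus baseline RMS (k configurable; a
silent noiseless trace is never called present).  The presence criterion
is a conventional electrophysiology heuristic — the original threshold
rule states only "minimum level still eliciting wave 1".  Thresholds are
called on a level sweep descending from 100 dB SPL (5 or 10 dB steps,
read from the data): minimum level of the present-run anchored at the
top; non-monotone presence sequences are flagged and resolved to the
longest contiguous run (nearest the top on ties), which avoids spuriously
low thresholds; all-absent sweeps are censored; all-present sweeps return
the lowest tested level with a "floor" flag.  Raising k can only raise a
called threshold.  Frequency-to-region: 4 and 12 kHz apex, 20 and 25 kHz
middle, 36 kHz base.

Cohort truth defaults: baseline thresholds 29/35/35 dB SPL
(apex/middle/base) with SEM-implied spreads at n = 6; post-exposure
shifts ~10/9/12 dB in the protected ear and ~65 dB (largely censored at
the 100 dB ceiling) in the unprotected ear, snapped to the level grid.

## Histology

Hair cells sit in four rows (IHC, OHC1-3) at supplied positions (percent
distance from apex — position measurement is treated as an input
coordinate, not inferred from images).  Scoring marks a cell present iff
the mean phalloidin intensity in its footprint exceeds an Otsu threshold
on the image, making the call invariant to intensity rescaling; blank
channels score all-absent, constant non-zero (saturated) images are
refused.  Pre-scored CSV grids can bypass image scoring entirely, so real
manual counts flow through unchanged.  The cytocochleogram aggregates to
percent missing per row and 5% position bin (bin width configurable; 5%
matches the granularity at which loss maxima are reported); empty bins
are missing data, never 0%.  Generator defaults: 3 fields per cochlear
subdivision, 12 cells per field; the noise-exposed loss profile peaks at
20-30% and 45-50% from the apex for OHC rows and in the apical 30% for
IHCs.  HO-1 group means are sized so the percent change from a
background of 100 reproduces the observed group levels (21.7 / 119.1 /
20.4%, NE-NH difference 97.4%); between-rat spread is the printed SEM
scaled by sqrt(n), and the unprotected ear carries a larger residual SD.

## Problem sizes and numerical choices

End-to-end image checks run at 96x96 (recovery, field invariance) —
the chain is resolution-independent, and the two-region phantom at 96x96
already exercises every stage including the smoothing halo at region
boundaries.  Statistical calibration uses 1000 null replicates per test
(binomial SE ~ 0.7% at alpha 5%), power checks 200 replicates.  Division
floor 1e-6 of the reference maximum; fit tolerance 1e-8; registration
upsampling 100 (0.01 px grid); REML optimizer tolerances 1e-10/1e-12 so
the balanced-design collapse holds to ~1e-8.

## Known limitations

- Registration is translation-only; rotational motion is neither
  simulated nor corrected.
- The mixed model supports exactly one random intercept level (rat) and
  two residual strata (ears); Satterthwaite df are not implemented — the
  containment df used here are exact in the balanced case and
  conservative otherwise.
- The ABR simulator models wave 1 only, with a fixed latency; waves
  II-V, latency-intensity functions and human ABR formats are out of
  scope.
- Histology rendering uses a regular lattice and Gaussian blobs; it does
  not model confocal stacks, stereology, or antibody-specific
  calibration.
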