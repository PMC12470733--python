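# Methods

## Data model

A trial is 30 s of quiet stance sampled at 100 Hz: a CoP displacement pair
(ml, ap) in mm from a force platform, and nine IMU channels (angular
acceleration X/Y/Z in deg/s², angular velocity X/Y/Z in deg/s, roll/pitch/
yaw in deg) from a waist-worn sensor. Timestamps are treated as
informative only — every estimator works on sample indices at a uniform
rate, so the CSV time column is never consulted. Units are fixed (mm,
deg); there is no auto-detection.

## Linear metrics

Path lengths are total variation sums of raw first differences at the
native rate; no detrending or filtering is applied first. The sway area is
the covariance-based **95% prediction ellipse**, area =
π·χ²₂(0.95)·√det S. The alternative (a confidence ellipse for the mean,
smaller by a factor of ~n) is a different convention; the prediction
ellipse is the standard posturography choice and is what the tests verify
(≈95% of large Gaussian samples fall inside it). A singular covariance
(collinear points) yields area 0 with a degeneracy flag rather than an
error.

## Nonlinear metrics

**Sample entropy.** m = 2 and r = 0.2·SD by default. Distance is
Chebyshev; self-matches are excluded; both B^m and B^{m+1} count pairs
among the N − m templates that admit an extension, so the estimator is
exactly affine-invariant (r scales with the SD, computed with the
population convention, ddof = 0). If no (m+1)-pair matches, +inf is
returned rather than an arbitrary cap; a constant series raises — silent
zeros would silently corrupt the group statistics downstream.

**Higuchi fractal dimension.** Curve lengths use the exact normalization
L(m,k) = [Σ|x_{m+ik} − x_{m+(i−1)k}|]·(N−1)/(⌊(N−m)/k⌋·k²), averaged over
all k offsets; FD is the unweighted least-squares slope of ln L(k) on
ln(1/k) over **every** k = 1..k_max (no log-spaced subset, no weights).
k_max = 100 by default with N = 3000 (k_max must stay below N/2). Offsets
whose sub-series degenerate are excluded with a warning.

**Wolf Lyapunov exponent.** The series is delay-embedded (dimension 5,
delay 10 samples = 0.1 s by default); the nearest neighbor outside a
Theiler window (delay·dim samples) is tracked over fixed evolution
intervals (3 samples), accumulating ln(d_after/d_before); when the
separation exceeds 10% of the scalar data range (or the neighbor runs off
the end of the data), the neighbor is replaced by the closest admissible
point that best preserves the orientation of the separation vector
(falling back to the plain nearest neighbor). The exponent is the
accumulated log divergence divided by the total evolved samples —
**natural log per sample step**, dimensionless. Its absolute scale depends
on every one of these knobs, which is why they are all exposed in the
config and echoed into the run manifest; only sign and ordering properties
are comparable across implementations. Recovery tests: the r = 4 logistic
map (embedding 2, delay 1, evolution 1) gives ≈ 0.65–0.67 against the
analytic ln 2 ≈ 0.693, within the 0.07 tolerance the folding of the map
admits for a neighbor-tracking estimator; a sine wave gives ≈ 0.

## Group statistics

Mann–Whitney U with a tie-corrected variance and (by default) a
continuity correction for Z; p comes from exact enumeration for small
untied samples and the normal approximation otherwise. Z is signed so
that a positive value means the first group (non-dependent, by pipeline
convention) tends larger; hence the dependence-history group having larger
sway shows as negative Z and r = Z/√N. Quartiles use linear interpolation
between order statistics. The Shapiro–Wilk gate is advisory: it is
computed and reportable, but the comparison is always rank-based, keeping
one uniform procedure across all variables. No multiple-comparison
correction is applied by default (each variable × condition is reported at
its nominal p); a Holm step-down option exists but only adjusts the
significance flags, never the reported p values.

## Correlation screen

Spearman rank correlation by default: it matches the rank-based framework,
is invariant to monotone transforms, and makes no normality assumption;
Pearson is available by configuration. The screen tests every sway metric
(10) against every IMU median (9) per group × condition, keeps p < alpha,
and labels strength bands on |ρ| (< 0.3 weak, < 0.5 moderate, ≤ 0.7
strong, < 0.95 very strong, else near-perfect). With no multiplicity
correction this is an exploratory screen: under the null the expected
false-hit count is alpha × 90 = 4.5 per stratum, which the null-calibration
test verifies directly. Constant channels are skipped with a warning
rather than failing the stratum.

## Synthetic cohorts

The generator reproduces the *statistical* structure the analysis needs,
not stance biomechanics:

* **CoP**: each axis is an independent fractional Brownian motion path
  (exact Davies–Harte circulant embedding), low-pass filtered (4th-order
  Butterworth, 10 Hz corner) into a physiological band, then linearly
  rescaled so the expected path length — estimated analytically as
  (n−1)·sd(Δx)·√(2/π) for Gaussian-like increments — equals a condition ×
  group target. Default targets are the published reference medians of the
  19 vs 28 cohort. Hurst defaults to 0.7, giving persistent, 1/f-like sway
  and raw-path FD 2 − H = 1.3, in the range reported for quiet stance.
* **Between-subject spread**: a log-normal factor (σ = 0.25 in log space)
  multiplies both axis targets per subject × condition. That value matches
  the reference tables' typical IQR/median ratios and gives the observed
  group contrasts the power the acceptance property requires; the
  reference source states no dispersion model.
* **IMU**: each channel is a constant subject level plus smooth AR(1)
  noise (φ = 0.95, amplitude = 0.5 × spread). Levels concentrate on
  per-channel baselines with additive offsets for the dependence-history
  group, both taken from the reference median/quartile grid; spreads are
  IQR/1.349 with a floor of 0.03 native units, because several gyroscope
  channels print quartiles of exactly 0 (sensor resolution) and a
  literal zero spread would make them degenerate for every statistic.
* **Seeding**: every per-trial seed derives from
  SeedSequence([master_seed, subject_index, condition_index, stream]),
  so cohorts are bit-reproducible and any single trial can be regenerated
  in isolation. Conditions are generated independently per subject — no
  within-subject correlation across conditions is modeled, as no such
  structure is published.

What passing tests therefore show: the estimators recover known systems,
the statistics are calibrated, and the pipeline detects contrasts of the
published magnitude at the published sample sizes. What they do not show:
that real CoP signals are fBm-like at fine scales, that real conditions
are exchangeable across subjects, or that the absolute nonlinear values of
real cohorts are matched — SampEn/FD/LyE levels depend on signal
smoothness and estimator parameters, so only their contrasts and
properties, not their absolute published values, are reproduced here.

## Problem sizes

Default trials are 3000 samples. The test suite uses 6 s (600-sample)
trials for pipeline plumbing and full-length trials wherever an estimator
property is asserted; replicate-cohort properties use 50 cohorts and the
null calibrations 1000 test simulations / 200 screen cohorts — sizes at
which the binomial error bands in the assertions are meaningful.

## Known limitations

* The Wolf exponent's absolute scale is parameter-bound (see above); no
  Rosenstein alternative is provided.
* The ellipse convention (prediction vs mean-confidence) changes absolute
  areas; cross-study area comparisons must check conventions.
* The generator's independent-axes assumption ignores ML/AP coupling;
  CoP_total contrasts still propagate correctly, but realistic planar
  trajectories would need a coupled model.
* Multiscale entropy, frequency-domain sway measures, and surrogate-data
  tests are out of scope.
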