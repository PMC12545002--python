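# Methods

This note documents the models, conventions and numerical choices behind
`ceustic`, and what the synthetic experiments do and do not demonstrate.

## Data model and intensity semantics

A cineloop is a `(time, row, column)` stack of finite, non-negative
intensities with strictly increasing per-frame timestamps (0-based indices,
row 0 at the top of the image).  The pipeline assumes **linearized
echo-power intensities**.  Vendor exports are sometimes log-compressed and
the export documentation rarely says which; rather than guess, a
`log_compressed` flag in the loop metadata triggers an explicit
delinearization `I → 10^(I/k)` (scale `k`, default 10 intensity units per
decade) via `delinearize`.  DICOM reading covers the basic multi-frame
layout only (`NumberOfFrames` with `FrameTimeVector`, `FrameTime` or
`CineRate`); vendor-private contrast tags are ignored, and missing timing
information is an error rather than a silent default.  The portable
container is a NumPy `.npz` archive (arrays plus a JSON metadata entry),
bit-exact on round trip.

## Motion compensation

Transrectal probe geometry makes small in-plane translation the dominant
motion artifact, so registration is **rigid translation only**.  Each frame
is compared with a chosen reference frame (default: the frame of maximal
mean intensity, which has the most structure) by exhaustive normalized
cross-correlation over integer shifts within ±`max_shift` pixels.  NCC is
invariant to affine intensity changes, which removes most of the
bolus-phase brightness swing between frames.  Details that matter:

* Correlation is computed on log-intensities; **moving** frames are
  additionally smoothed by a 3-frame temporal moving average to damp
  speckle.  The **reference is left unsmoothed**: temporal averaging would
  blend in neighbouring frames at other displacements and bias (or, for
  abrupt shifts, split) the correlation peak.
* Ties at the peak are broken toward the smaller displacement norm, then
  lexicographically (row, then column) — estimates are fully deterministic.
* Subpixel refinement (default on) fits a separable quadratic through the
  peak's 3-point neighbourhoods; the offset is clamped to ±0.5 px.
* Correction resamples each frame by the negated shift (bilinear by
  default; nearest-neighbour available, exact for integer shifts), filling
  out-of-field pixels with edge values and flagging the fact in metadata.
* A zero-variance reference raises a "degenerate reference" error; a flat
  *moving* frame contributes a zero shift rather than an error.

On simulator drift (3 px sinusoidal amplitude, 5% noise), recovery error is
≤ ~0.2 px and re-estimation after correction leaves < 0.1 px residual.
Note the *relative* drift between two frames can reach twice the amplitude,
so `max_shift` should be chosen accordingly.

## TIC landmarks and the wash-in gradient

Per pixel, the raw trace is smoothed with a centered moving average
(default window 5 frames, edges truncated so constant traces are preserved).
Landmarks:

* **baseline** — mean of the smoothed trace over the first
  `max(3, ⌈0.05·T⌉)` frames.  Basing the baseline on a fixed initial window
  breaks the circularity between baseline and start detection (the start
  threshold depends on the baseline and vice versa): the pre-arrival window
  is defined once, then the start is found against it.
* **peak** — global maximum of the smoothed trace; ties resolve to the
  earliest frame (wash-in semantics).  A maximum on the final frame means
  washout was never observed; the pixel is flagged `censored_peak`.
* **enhancement start** — first upward crossing of
  `baseline + θ·(y_peak − baseline)` before the peak, linearly interpolated
  between samples.  The threshold is a *fraction* θ (default 0.05) of
  peak-above-baseline rather than an absolute intensity, so it is invariant
  to gain settings.
* Pixels with `y_peak − baseline` below an absolute `noise_floor`
  (default 10⁻⁶ intensity units) are flagged `no_enhancement`.

The **mean gradient to peak** is the endpoint-difference quotient
`(y_peak − y(t_start)) / (t_peak − t_start)`: the time-average of the
instantaneous wash-in slope telescopes to exactly this ratio.  The lower
endpoint defaults to the threshold-crossing intensity (`gradient_from:
start_intensity`, the literal "start of enhancement to peak" reading); a
`baseline` variant is config-exposed since vendor conventions differ.  The
map stores NaN wherever quality is not `ok`, with the reason in a parallel
quality grid (`no_enhancement`, `censored_peak`, `degenerate_interval`).

The computation is exactly scale-equivariant (intensities ×c scale the map
by c, provided the absolute noise floor is scaled too) and invariant to
time-origin shifts, and it is deterministic — properties the test suite
asserts bit-exactly.

## Parametric map rendering

In-mask `ok` pixels are coloured by min–max (or percentile) normalization
through a matplotlib colormap (default `jet`, cool→hot); other pixels show
the grayscale reference frame if provided.  A colour bar with numeric ticks
is embedded in the saved figure.  Constant maps render a single colour with
a logged warning, not an error.

## Discreteness grading

The four-tier classification of hot-region spatial patterns is, in visual
practice, a subjective call; here it is an explicit rule so it is
reproducible and auditable.  Hot pixels are `ok` in-mask pixels at or above
a threshold — the 75th percentile of in-mask values by default at the
function level, or Otsu's threshold on the in-mask histogram.  **The
end-to-end pipeline defaults to Otsu**: a fixed percentile pins the hot
area at a fixed fraction of the ROI, which manufactures spurious scattered
components whenever the truly hyper-perfused area is smaller than that
fraction; Otsu adapts to the histogram's two modes.  Components are
8-connected (matching the visual contiguity of rendered blobs); components
below `min_area` (default 5 px) are discarded as speckle singletons.

With `n` components and dominant area fraction `d` (largest component /
total hot area), the default rule is:

| grade | condition | pattern |
|---|---|---|
| 1 | n = 1 | single focal contiguous area |
| 2 | 2 ≤ n ≤ 4 and d ≥ 0.70 | dominant area + few satellites |
| 4 | n ≥ 6 and d < 0.35 | numerous scattered foci |
| 3 | otherwise | multiple distinct areas |

All cutpoints are configurable; the feature vector (component areas,
centroid dispersion normalized by the ROI equivalent diameter, threshold
used) is always reported so a human can audit the call.  Dispersion is
computed but deliberately not used by the default rule — it is reported for
sensitivity analyses.  An empty hot set yields an explicit "undefined"
grade (0), distinct from 1–4.  The rule is invariant to component
relabelling, and merging components never increases the grade.

## The simulator

`ceustic.synth` emulates a bolus-transit acquisition, not acoustics: no
point-spread function, no nonlinear microbubble response, no washout-phase
pathology.  Per pixel the noiseless trace is a **gamma-variate**
indicator-dilution curve

`y(t) = baseline + ymax · u^α · exp(α(1−u))`, `u = (t−t0)/(tpk−t0)` (0 for t ≤ t0),

which is `baseline` before arrival and peaks at exactly `baseline + ymax`
at `tpk`.  Defaults: background `t0 = 10 s, tpk = 40 s, ymax = 20,
baseline = 5, α = 1.5`; lesions have double the peak enhancement over half
the wash-in interval (`tpk = 25 s, ymax = 40`), i.e. a 4× wash-in gradient —
a contrast chosen for realism, not fitted to any cohort.  The shape
α = 1.5 is a typical first-pass bolus; with the default 5% start threshold
the endpoint-quotient estimate of the slope then sits within ~0.3% of the
analytic `ymax/(tpk−t0)`, so phantom-recovery error is essentially
discretization and noise.  The per-pixel analytic gradient map
(`gain · ymax/(tpk−t0)`) is carried as ground truth.

On top of the kinetics:

* a **static speckle-texture gain** per pixel (default σ = 0.05),
  band-limited (Gaussian-filtered white noise, 1.5 px correlation length —
  the grain size real speckle inherits from the PSF).  It moves with the
  tissue, giving registration something to lock onto in pre-arrival frames;
  white-noise texture would decorrelate under subpixel resampling.
* **multiplicative frame noise** `I·(1 + σ·ε)`, clipped at 0 (σ relative;
  recovery experiments use σ = 0.1, i.e. ~10% of signal).  Full Rayleigh
  speckle statistics are out of scope.
* optional **sinusoidal rigid drift** bounded by `motion_amplitude`
  (different frequency and random phase per axis) — smooth, exactly known,
  and invertible for registration testing.

The four archetype layouts (one 14 px disc; a dominant disc + three 3 px
satellites; three 7 px discs + two sub-min-area foci; ten 3 px foci) are
laid out inside the elliptical "gland" ROI with per-seed positional jitter,
and validated to lie inside the ROI.  All randomness flows through one
`numpy` generator seeded per call: same seed, bit-identical phantom.

The ratings simulator draws ground truth Bernoulli(prevalence) and each
rater's binary call conditionally on truth at a stated
sensitivity/specificity, independently across raters and cases.  Real
readers are correlated (shared images, shared training); the conditional
independence model is the right null for calibration checks and for
operating-point arithmetic, but it understates between-reader agreement —
ICC/kappa values from simulated panels are not comparable to a real
panel's.

**What passing phantom tests shows** — the estimator recovers the wash-in
slope and the spatial pattern the generator encodes, under speckle-like
noise and rigid drift.  **What it does not show** — robustness to
attenuation, shadowing, out-of-plane motion, nonlinear bubble response, or
real prostate anatomy; those enter only through real cineloops.

## Reader statistics

All estimators are implemented from their definitions:

* **ICC** — two-way random effects, absolute agreement.  Single-measure
  ICC(A,1) is the default (individual readers' reproducibility is the
  question); average-measure ICC(A,k) is available.  Confidence intervals
  use the McGraw & Wong (1996) F-distribution method; the p-value tests
  ICC = 0 via `F = MSR/MSE`.  Zero between-case variance returns ICC 0
  with a degeneracy flag rather than raising.
* **Fleiss' kappa** — 1971 definition; the standard error is the
  Fleiss–Nee–Landis large-sample null SE, used for both the test and the
  normal CI (a single SE convention, stated rather than mixed).  For
  between-panel comparisons the package reports both Fleiss kappa over the
  pooled panel and Cohen's kappa between per-case majority calls, since
  "agreement between two reader groups" is ambiguous between the two
  constructions.
* **McNemar** — uncorrected `(b−c)²/(b+c)` by default, with an automatic
  exact-binomial fallback when `b + c < 25`; continuity-corrected and
  forced-exact variants are config options.  Zero discordance returns
  p = 1 with a flag.
* **Cochran-Armitage** — scores 1..K by default; z is invariant to affine
  rescaling of the scores, and single-class tables return a zero-variance
  flag.
* **Proportions** — exact Clopper-Pearson intervals by default (Wilson
  optional).
* **AUC** — Mann-Whitney with half-weighted ties, variance and paired
  comparison by DeLong's placement-value method.  For binary calls the AUC
  equals `(Se + Sp)/2` exactly; pooling 4 raters × n cases as 4n
  observations reproduces the single-operating-point analysis of a pooled
  panel, and per-rater averages are reported alongside.
* No multiple-testing adjustment is applied; the report says so in its
  metadata.

Independent cross-checks in the tests: a brute-force ANOVA recomputation of
ICC (≤ 10⁻¹⁰ agreement on random matrices), `pingouin`'s ICC table,
`statsmodels`' Fleiss kappa, definitional summations for kappa and the
trend test, and a 2000-replicate bootstrap for the DeLong variance (within
15%).

## Problem sizes and numerical choices

Validation experiments use 128×128 frames, 240 frames at 0.5 s (a 120 s
transit), ~6.5 k ROI pixels; discreteness recovery runs 50 seeded phantoms
per archetype at noise σ = 0.1 (recovery ≥ 90% per type, observed 100%),
and null calibration uses 2000 simulated tables per test.  These sizes make
the whole suite and the acceptance script run in a few minutes on one CPU
while keeping Monte-Carlo error well inside the asserted bands.  Under
σ = 0.1 multiplicative noise the *distribution* of per-pixel gradient
errors has heavy tails (the peak of a smoothed noisy trace is an extreme
value), so noisy recovery is summarised by the mean pixel-wise relative
error (~14%); the noiseless case is asserted pixel-wise (max error ~1.6%).

## Known limitations

* Rigid translation only; elastic deformation and out-of-plane motion are
  not modelled or detected.
* No TIC model fitting (no gamma-variate regression per pixel) and no
  washout parameters — the wash-in endpoint quotient is deliberately
  model-free.
* The discreteness cutpoints are declared defaults, not fitted to data;
  they are exposed precisely so they can be calibrated against a cohort.
* The units of the gradient are linear-intensity/s; comparisons across
  machines require consistent gain and linearization.
* Binary reader calls only; ordinal/confidence ROC and hierarchical
  multi-reader multi-case models (e.g. Obuchowski-Rockette) are out of
  scope.
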