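# Methods

## The analysis model

The pipeline quantifies *interbrain coherence*: time- and frequency-resolved
phase-locking between the BOLD signals of two simultaneously scanned
participants.  For each dyad, ROI and run, both subjects' extracted ROI
series (first eigenvariate level; the pipeline does not touch volumetric
data) are transformed with the analytic Morlet continuous wavelet transform
and combined into magnitude-squared wavelet coherence

    R²(s, t) = |S(s⁻¹ · Wx(s,t) · Wy*(s,t))|²
               ─────────────────────────────────────────────
               S(s⁻¹ · |Wx(s,t)|²) · S(s⁻¹ · |Wy(s,t)|²)

with `S` a smoothing operator acting first in time (Gaussian,
SD equal to the scale, matching the Morlet envelope) and then across scales
(centred boxcar over 12 scales).  Both kernels are renormalised where they
overhang the record or grid edge, so `S` maps constants to themselves and
Cauchy–Schwarz guarantees R² ∈ [0, 1].  Without smoothing R² would be
identically 1; the smoothing width therefore sets the effective number of
independent cross-spectral estimates entering each coherence value.

### Wavelet and grid

* Morlet centre frequency ω₀ = 6 rad (the standard admissible choice;
  parameter of `build_scale_grid`).  Scale and frequency are related by the
  Fourier factor 4π/(ω₀ + √(2+ω₀²)) ≈ 1.033.
* Scales are geometric at `voices` per octave, anchored at `f_max`:
  count = ⌊voices·log₂(f_max/f_min)⌋ + 1.  The defaults
  (12 voices, 3.9–289.4 mHz, TR 1.5 s) give 75 scales, ordered
  high-frequency → low-frequency throughout the package.
* The CWT is computed by frequency-domain multiplication with L2-normalised
  daughters, zero-padded beyond the kernel support so it equals a direct
  linear convolution with the sampled time-domain wavelet (the test suite
  enforces 1e-8 agreement against a brute-force convolution oracle).  The
  kernel spectra are periodised over the sampling rate: near Nyquist the
  Morlet response has not decayed, and without the alias terms the smallest
  scales acquire padding-dependent ringing at the 1e-6 level.
* Signals are mean-removed but not variance-normalised (coherence is
  amplitude-invariant; a test asserts invariance under x → a·x + b).
* Cone of influence: a point is trusted when its distance to the nearer
  record edge exceeds √2·s, the e-folding time of the wavelet envelope.
  In-block samples outside the COI are *included* in term extraction by
  default (`use_coi_mask=True` enables masking for sensitivity analyses);
  block windows sit in the record interior where the band-of-interest
  scales are inside the cone anyway.

### Band selection

The per-ROI coherence spectrum averages R² over dyads and all in-block time
points.  Frequencies above 220 mHz and below 9.6 mHz are trimmed (sampling
and transform artifacts at the extrema).  On the grand-mean curve the band
of interest is read from slope extrema computed by central differences on
the scale index (the grid is geometric, so index differences are log-
frequency derivatives): the peak at the curve maximum, the high edge at the
steepest rise on the high-frequency side, the low edge at the steepest fall
on the low-frequency side.  Slope ties are resolved toward the scale
farthest from the peak (with a 1e-9 relative tolerance, so exactly linear
flanks choose their outermost point).  A curve without a strict interior
maximum raises a no-band error — deliberately: on a null cohort the curve
is flat and a "selected band" would be noise; calibration experiments use
an explicit band override instead (0.08–0.15 Hz in the tests, the band the
procedure recovers on coupled cohorts).  Band edges are inclusive.

### Term extraction and baseline correction

Block windows run from the first trial onset + 5 s (hemodynamic delay;
half-open ceil/floor index rounding keeps every sample inside the block) to
the end of the last trial's feedback.  One term per dyad × block × ROI is
the mean R² over band scales and window samples; terms are averaged over
runs, and solo + watch blocks are pooled into a single control condition
(the two roles cannot be separated at the dyad level, as the partner always
holds the complementary role).  ROIs whose data are unusable in more than a
third of dyads are dropped entirely.

The surrogate ("fake-dyad") baseline re-pairs every subject with each
opposite-scanner subject except the true partner — with n dyads that is
n−1 pairings per subject, exhaustive and therefore seed-independent; a
random subset is drawn only when `n_permutations` is set below n−1.
Surrogate pairs never share a scanner, so scanner-specific artifacts cannot
enter the baseline.  Surrogate extraction reuses the same band and the
intersection of the two subjects' block windows (identical under the shared
schedule).  The dyad-level baseline is the arithmetic mean of the two
members' subject baselines (symmetric default; `subject-a`/`subject-b`
strategies available), subtracted cell-wise from the raw terms.  The key
calibration property — coherence driven purely by the common task schedule
appears equally in surrogate pairs, so corrected values on uncoupled
cohorts are centred on zero — is verified end to end in the test suite
(20 dyads × 50 ROIs).

### Group statistics

Order of operations: baseline subtraction → Fisher z (atanh, values clipped
to |v| < 1−1e-7; a flag applies the transform to signed square roots
instead) → outlier removal → repeated-measures ANOVA.  Outlier removal per
ROI × condition: a 1.5-IQR fence, then iterative removal of the value
farthest from the median until |skewness| < 1 and |excess kurtosis| < 2
(Fisher convention, normal = 0; biased sample moments), with a floor of 70%
of the original values and a 5-value minimum below which the cell is
excluded.  The ANOVA is the classical one-way within-subject decomposition
(complete cases, listwise per ROI); sphericity is tested with Mauchly's W
on the orthonormal-contrast covariance using the first-order chi-square
approximation, and when its p < 0.05 both degrees of freedom are multiplied
by the Greenhouse–Geisser ε (bounded to [1/(k−1), 1]).  Omnibus p-values
are BH-FDR corrected across ROIs at q = 0.05 (statsmodels implementation;
an exhaustive step-up oracle checks it in the tests).  Post hoc two-tailed
paired t-tests are limited to contrasts containing cooperation
(vs solo, communication, competition) and FDR-corrected jointly across all
contrasts × significant ROIs (a per-contrast family is a flag away).
Mauchly's p uses the first-order approximation; the reference
implementation (pingouin) applies a higher-order Box term, which shifts p
by ~0.02 far from the threshold — W, χ², ε and the ANOVA table itself agree
to machine precision, and a 500-replicate null simulation confirms the
test's calibration.

## The synthetic cohort

`simulate_cohort` emulates the study design the analysis targets, so the
generator's defaults *are* the study conditions:

* TR = 1.5 s, two runs of 775 volumes, one dyad per scanner pair
  (scanner-1/scanner-2 labels).
* Five blocks per run in fixed order — cooperation, communication,
  competition, solo, watch — with the solo/watch roles swapped in run 2 and
  no order randomisation across dyads.  Trials: 5 s planning, a stimulus
  delay uniform around a 1.05 s mean, a 2.5 s response slot, and feedback
  whose duration is yoked to the delay (2.55 s mean) so every trial lasts
  11.1 s.  Trial counts and rest durations are free parameters of such
  designs; the defaults (18 trials/block, 15 s inter-block rest, 12 s
  lead-in) fill ~1070 s of the 1162.5 s run, leaving a realistic tail of
  rest.  The stimulus-delay sequence is shared by all dyads (schedule RNG
  stream), as in a non-randomised design.
* Noise: per subject × run × ROI AR(1) with coefficient 0.3 and unit SD
  (a realistic lag-one autocorrelation for eigenvariate-level BOLD after
  high-pass filtering), optionally 1/f-shaped via a spectral exponent.
* Coupling: per coupled cell, a narrow-band analytic process (8 random
  tones in the configured band) is added to both members during that
  condition's blocks — identical up to the configured phase lag and scaled
  to `amplitude` × noise SD.  Injection is additive at the extracted-series
  level; no hemodynamic convolution, since the analysis operates on
  eigenvariate-level signals.
* RNG streams are keyed (seed, stream, unit): per-subject noise, per-dyad
  response times and coupling, one schedule stream, one missingness stream.
  Adding dyads to a config therefore never perturbs existing ones, and a
  seed reproduces the cohort bit for bit.  Shared coupling components are
  necessarily dyad-keyed rather than subject-keyed.
* Response times come from a correlated bivariate Gaussian per condition
  (floored at 50 ms), with means below 1.6 s in the competition/solo
  regimes to exercise the fast-response adjustment in the scoring rules.

What the generator does **not** emulate: volumetric data and spatial
structure, motion and physiological artifacts, hemodynamic convolution of
the coupled component, inter-dyad timing jitter, or non-stationary noise.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its own model assumptions (calibration of the surrogate baseline,
sensitivity to genuine phase-locked coupling), not robustness to every
property of scanner data.

The demonstration signal pair (`demo_signal_pair`) — partially overlapping
5 and 40 mHz sine components against matching cosines plus independent
Gaussian noise — reproduces the classic two-cluster WTC illustration with a
π/2 cross-phase; the component on/off intervals are parameters.

## Numerical choices and degenerate inputs

* Scale-count formula uses ⌊·⌋ on voices·log₂(f_max/f_min); a degenerate
  f_min = f_max grid has one scale.  f_max at or above Nyquist is an error.
* Half-open block windows (ceil start, floor end) make consecutive blocks
  disjoint by construction; blocks shorter than the hemodynamic exclusion
  are reported and skipped, not fatal.
* Zero-variance series raise a degenerate-input error in `wtc`; constant
  paired differences in post hoc tests are treated as the t → ∞ limit
  (p → 0) or t = 0, p = 1 when the difference is identically zero;
  a zero-error-variance ANOVA cell is flagged and excluded.
* Surrogate computation evaluates coherence only on the band's scale rows
  plus the boxcar margin; edge renormalisation is applied relative to the
  full grid, so the fast path is bit-compatible with the full computation
  (enforced by a test at 1e-9).
* The checkpointed pipeline stores per-block per-scale coherence means
  (blocks × 75 values) instead of full maps, keeping tens of dyads ×
  hundreds of surrogate pairings within desktop memory.

## Problem sizes used in the shipped experiments

The end-to-end calibration test uses 20 uncoupled dyads × 50 ROIs (≈ 2
minutes); the recovery test uses 30 dyads × 8 ROIs with coupling in two
ROIs (≈ 40 s); module-level tests run on 4-dyad cohorts with shortened
runs.  These sizes give standard errors small enough for the stated
acceptance margins while keeping the default test run short.

## Known limitations

* Mauchly's p-value uses the first-order chi-square approximation (see
  above); for n ≥ 10 the difference from the higher-order form is
  immaterial to the 0.05 gate.
* `remove_outliers` recomputes the median after each removal but applies
  the IQR fence once, as a first pass; pathological multimodal cells can
  retain structure the moment criteria do not detect.
* The empirical band selector requires a strict interior peak; cohorts
  without task-locked coherence need a band override.
* The CLI executes serially; dyad × ROI computations are independent, so a
  parallel map would be a drop-in change, and `--threads` is accepted but
  currently ignored.
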