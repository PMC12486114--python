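# Methods

This note documents the models, statistics and design choices behind
`neuromodml`, the way a maintainer (rather than a tutorial reader) needs
them: what is computed, under which conventions, with which defaults, and
what the synthetic test bed does and does not establish about real data.

## Problem setting

Intermittent theta-burst stimulation (iTBS) over left primary motor cortex
produces highly variable neurophysiological after-effects.  The package
implements an end-to-end analysis for asking whether baseline measures —
resting-state EEG (rsEEG) band powers and temporal complexity, plus
pre-stimulation TMS-evoked features — predict who will show corticospinal
(MEP) or cortical (TEP/LMFP) modulation, in a two-cohort test-retest
design, and for diagnosing *why* such models fail to generalize
(covariate shift vs. label shift vs. concept drift).

## Outcome definitions

* **MEP responder**: two-tailed two-sample t-test between pre- and
  post-stimulation MEP peak-to-peak amplitudes; responder iff p ≤ 0.05
  (inclusive), direction-agnostic.  Pooled-variance Student's test by
  default with Welch as a config switch — the variant is not determined by
  the method description we follow, so both are exposed.
* **LMFP facilitation**: the local mean field power over the left-motor
  ROI {C1, C3, C5, FC1, FC3, FC5} is the per-time-point RMS of voltages
  across those channels (SD-about-the-ROI-mean is available as an
  alternative operator).  Per trial, the LMFP curve is integrated over a
  time window with the composite Simpson rule; per-trial AUCs are averaged
  within block; facilitation iff mean post / mean pre ≥ 1 (inclusive).
* **Windows**: 43 categorization windows by default — four a priori
  windows (15–45, 15–80, 100–131, 105–135 ms) plus 39 swept 30-ms windows
  with starts evenly spaced over 25–315 ms.  The exact swept list used in
  the original analyses is not published; this reconstruction preserves
  the count and the sweeping rule and is fully configurable.  Window lists
  are recorded in output metadata.
* **Simpson on even sample counts**: composite Simpson on the largest odd
  prefix plus a trapezoid on the final interval (logged); with fewer than
  3 samples the integral falls back to a trapezoid with a warning.

## Baseline features

* **Band powers**: multitaper PSD per channel on consecutive
  non-overlapping 10-s epochs from t = 0, DPSS tapers with NW = 4 and
  2·NW − 1 = 7 tapers, uniform weighting, demeaned epochs; one-sided
  density in µV²/Hz, Parseval-consistent with the epoch variance.  Band
  powers are the trapezoidal area under the PSD over delta 1–4, theta
  4–8, alpha 8–12 and beta 12–20 Hz (closed intervals: shared edges
  belong to both neighbouring bands) and are averaged across epochs.
  Taper count and weighting are package defaults — the upstream analysis
  names only "multitaper".
* **Complexity battery (18 measures per channel)**, computed once on the
  concatenated first six 10-s epochs (a 1-minute series):
  - single-scale: approximate entropy (m = 2, r = 0.2·SD, self-matches
    included), sample entropy (m = 2, r = 0.2·SD, self-matches excluded),
    permutation entropy (m = 3, normalized by ln m!, ties broken by order
    of occurrence), distribution entropy (m = 2, 512-bin histogram of all
    pairwise Chebyshev embedding distances, base-2 entropy normalized by
    log2 bins), increment entropy (m = 2, resolution R = 4, word entropy
    normalized by m·log2(2(R+1))), and Lempel-Ziv complexity (LZ76 phrase
    count of the median-binarized series, normalized by n/log2 n);
  - multiscale complexity indices: permutation entropy (m = 2 and 3),
    sample entropy and distribution entropy under three procedures —
    coarse-graining (offset-0 window means), composite (entropies averaged
    over all τ coarse-graining offsets) and time-shifted (entropies
    averaged over the τ lag-subsampled subsequences) — over scales 1..20,
    summarized as the trapezoidal area under the entropy-versus-scale
    curve.  Multiscale sample entropy keeps r fixed at 0.2·SD of the
    scale-1 series (the standard multiscale convention; recomputing r per
    scale would make the curve flat for white noise).
  ApEn/SampEn/DistEn/IncrEn parameter values are package defaults exposed
  in config; the original per-measure settings table is unavailable.
  Non-finite entropies (e.g. SampEn with no template matches at high
  scales) are propagated as missing; sessions missing a selected feature
  are dropped from that model's fit, with logging.
* **Pre-stimulation TMS features**: mean and SD of baseline MEP
  amplitudes, the mean LMFP AUC over 15–80 ms, and a TEP regression
  quality score.  The RQS here is a deliberately simple trial-consistency
  score — the mean R² of regressing each trial's ROI-averaged waveform on
  the block-mean waveform, clipped to [0, 1] — documented as a stand-in
  for the published composite it replaces.  The MEP experiment uses all
  four features; the LMFP experiment uses only the two TEP-derived ones.

## Shift and reliability diagnostics

Per feature, a two-sample Kolmogorov-Smirnov test (asymptotic p) between
initial and retest sessions probes covariate shift; per categorization
method, a two-tailed Fisher exact test on the class-by-visit 2×2 table
probes label shift.  No multiple-testing correction is applied — rejection
*fractions* are reported, matching how the diagnostics are meant to be
read.  Reliability uses ICC(1,1) from one-way random-effects ANOVA mean
squares, (MSB − MSW)/(MSB + MSW) for two sessions with the F-test p, for
continuous measures; Cohen's kappa with the Fleiss large-sample z-test for
binary outcomes; and the percentage of participants with the same outcome
on both visits.  Only participants with both visits enter the paired
statistics; all sessions enter the two-sample tests.

Concept drift has no direct test.  The verdict is policy: drift is
suspected when the KS and Fisher rejection fractions both stay ≤ 2α (no
widespread shift) while the mean outcome ICC falls below 0.2 (low
reliability).  Both thresholds are explicit, configurable package choices.

## Model search

Feature groups = ROI × transform × feature set.  ROIs: left motor (6
channels), central (default {FC1, FC2, C1, Cz, C2, CP1, CP2} — a
documented placeholder, the published channel table being unavailable) and
whole scalp.  Transforms, both fit on training data only: z-score, and
log-distance x̃ = log10 x − log10 median(train).  The feature-set universe
is 4 bands + 18 complexity measures + 4×18 pairs = 94.  Pre-stimulation
features are appended to every group (transformed with the group; a raw
option exists); the cross-cohort design appends a binary visit-type
indicator, which passes through transforms unchanged.

Nine classifiers (scikit-learn backed): logistic regression with L2
penalty and inner-CV-tuned strength (grid 10⁻³..10³, 7 points; an L1
switch exists because the source description is ambiguous between ridge
and lasso), LDA with inner-CV-tuned shrinkage (grid 0..1, 11 points), LDA
with Ledoit-Wolf and with OAS covariance, nearest-centroid with Manhattan
and with Euclidean metrics (shrinkage threshold 0 by default; continuous
scores are the difference of distances to the two centroids), Gaussian
naive Bayes with empirical priors and with fixed 80–20 priors (0.8 on the
positive class by default), and a Gini decision tree (unlimited depth,
seeded).  Inner CV is 5-fold stratified, adapting down when a class is
smaller than the fold count.

Evaluation: 10 repetitions of 5-fold stratified CV (repetition r seeded
with master_seed + r), 50 held-out folds, seven metrics (accuracy,
sensitivity, specificity, F1, precision, ROC-AUC, PR-AUC), Student-t 95%
CIs over folds.  Metrics undefined on a fold (e.g. precision with no
positive predictions) are flagged missing and excluded from that
aggregate.  Selection: models with mean sensitivity or specificity below
0.60 are excluded; the highest mean ROC-AUC wins, ties broken
lexicographically on the model id.  The winner is refit on the whole
training set and scored on the external set with percentile 95% CIs from
2000 class-stratified bootstrap resamples (each resample preserves the
validation class counts exactly).  Gini feature importances are reported
for decision-tree winners.

Designs: cross-session (train on initial visits, validate on retests) and
cross-cohort (train on cohort 1, validate on cohort 2, visit type
appended).

## Synthetic cohort

The generator emulates the reference study's structure: cohort 1 with 15
both-visit, 2 initial-only and 4 retest-only participants (36 sessions),
cohort 2 with 18 both-visit and 1 retest-only (37 sessions) — 73 sessions,
35 initial and 38 retest.  Full-scale signal defaults follow the
protocol: 32-channel 10-10 montage containing the LM channels, 1000 Hz,
180-s rsEEG, 150/150/60 (cohort 1) and 120/120/60 (cohort 2) trials for
pre/T5/T25 blocks.

Generative model and ground-truth linkage:

* Each participant carries a stable binary **trait** (responder fraction
  0.5 by default).  The trait scales the rsEEG oscillator amplitudes
  (default ×1.5 for trait = 1) on *both* visits, inducing a recoverable
  class signal in band powers and complexity.
* Each visit carries a binary **state**: the initial state equals the
  trait; the retest state equals it with the label-consistency
  probability and is flipped otherwise.  The state (not the trait) drives
  the outcome blocks: MEP post-blocks get a 1.5-SD log-scale shift for
  state = 1; TEP post-blocks get LMFP gain 1.3 (state = 1) or 0.8
  (state = 0).  Labels are re-derived downstream from the blocks, never
  copied, so label derivation is itself under test.
* Default label consistency is 0.5, matching the ~50% outcome consistency
  observed empirically in this paradigm; consistency 1.0 yields the
  generalization regime, 0.5 the concept-drift regime (stable features,
  unreliable outcomes, CV-to-external performance collapse).
* rsEEG = 1/f^β background (β = 1, 10 µV RMS) + brick-wall band-limited
  oscillators (delta/theta/alpha/beta at 4/3/6/2 µV RMS) + 2 µV white
  sensor noise.  Amplitude scales are package choices; no reference values
  exist for them.
* TEPs = a shared template of Gaussian-windowed sinusoids with component
  peaks near 15, 30, 45, 60, 100 and 180 ms (left-motor channels weighted
  1.0, others 0.4), scaled by the block gain, plus white trial noise.
  Trial noise defaults to 0.5 µV: per-trial RMS rectifies additive noise
  and biases window-AUC ratios toward 1, and 0.5 µV keeps the mean
  recovered ratio within ±0.05 of the injected gain — the contract the
  generator must satisfy for parameter-recovery testing.  Waveform shape
  is unconstrained by the source; only pre/post LMFP ratios matter
  downstream.
* MEP amplitudes are log-normal (µ = 0, σ = 0.5 on the log scale, mV).

What the generator does **not** emulate: volume conduction or any forward
model, spatial correlation structure across channels, TMS pulse artifacts,
blinks/muscle noise, non-stationarity within a recording, or preprocessing
effects.  Passing tests therefore establish the correctness and
calibration of the *analysis chain* under a known generative model — not
that real rsEEG complexity predicts real iTBS response.

## Problem sizes and numerical choices

Tests and the acceptance script use a reduced-scale spec (8 channels,
64 Hz, 60-s rsEEG, 250 Hz TEPs, 20–30 trials) and measure subsets — the
package's own choice of desk-scale study conditions; the full-scale
defaults remain available behind `full_scale: true`.  The null-calibration
simulation uses 1000 units with 200 observations per visit for the KS and
Fisher tests: Fisher's exact test is conservative on small tables, and at
these sizes its empirical null rejection (~4%) sits inside the binomial
99% band around α = 0.05, so calibration is a meaningful check rather
than a guaranteed under-rejection.  MEP calibration uses 60 trials per
block.

Entropy computations switch from dense Chebyshev distance matrices to
KD-tree neighbour counting above 1200 templates; sample entropy uses exact
pair counting (`count_neighbors`); distribution entropy uses C-level
`pdist` up to 6000 templates and a chunked two-pass histogram beyond.
All are exact algorithms — the switches change speed, not values (verified
against brute-force oracles to 1e-10).

Degenerate inputs: a constant series returns 0 for ApEn (with a warning),
SampEn, DistEn and IncrEn; SampEn with no (m+1)-matches returns +inf and
is flagged; an all-zero generator spec, a zero-variance TEP mean waveform
and a zero pre-block LMFP AUC are rejected as data errors.

## Reproducibility

Every random draw flows from one master seed through named CRC-derived
substreams; generators are pure functions of (spec, seed).  `run_pipeline`
writes a manifest with the config snapshot, package version, seed, SHA-256
digests of all CSV/JSON outputs and per-stage timings; re-running a
manifest reproduces identical digests.

## Known limitations

* The RQS is a simplified stand-in, not the published composite score.
* The 43-window list and the central-ROI channel list are reconstructions
  (count- and rule-faithful, not value-faithful).
* The real-cohort result tables cannot be reproduced without the original
  data; the package validates structure, calibration and qualitative
  phenomena (generalization under consistent outcomes, drift under
  inconsistent ones) instead.
* Session-level EDF export is not provided; the on-disk layout is
  .npy + JSON sidecars with CSV for MEP amplitudes.
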