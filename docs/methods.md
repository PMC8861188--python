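# Methods

This note documents the models and procedures implemented in `voicelung`,
the parameters that matter, the synthetic-data generator's assumptions, and
the numerical conventions. Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Problem setting

The target is FEV₁% predicted, measured by spirometry immediately after each
voice recording of a subject reading aloud. The working hypothesis is that
airway obstruction leaves measurable traces in the recording: breath sounds
become more intense relative to speech, respiratory rate rises (breath
onsets come closer together), and breath spans lengthen. The pipeline
extracts acoustic summaries of the breathing and speech portions separately
and regresses lung function on them.

## Frame-level features

All features are computed on centre-padded frames (zero padding of
`frame_length/2` on both ends), so frame *i* is centred at `i·hop/sr`.
Defaults: 22 050 Hz, frame 2048, hop 512, Hann window — the conventional
analysis grid for speech at this rate; all are configurable via `FrameGrid`.

Time-domain features use the raw (unwindowed) frame: `rms = sqrt(mean(x²))`,
`mean_amp = mean(|x|)`, and zero-crossing rate = sign changes / (N−1).
Spectral features use the magnitude spectrum of the Hann-windowed frame:
centroid and bandwidth are the first two moments, roll-off(q) is the lowest
frequency accumulating a fraction q of total magnitude (q = 0.85, 0.95).
Spectral flatness is the geometric/arithmetic mean ratio of the **power**
spectrum, matching the usual convention (≈1 for noise, →0 for tones).
Spectral contrast is the mean over six octave sub-bands above 200 Hz (capped
at Nyquist) of the dB gap between the top-2% and bottom-2% of magnitudes in
the band (at least one bin each).

Numerical conventions: an ε = 1e−10 floor is applied inside all logarithms
and the flatness ratio, so an all-zero frame has flatness 1 and contrast 0;
centroid, bandwidth and roll-off of an all-zero frame are defined as 0.
These conventions only matter for silent frames, which the generator never
produces but real recordings might.

Every spectral feature is verified in the test suite against a plain-loop
recomputation from an O(N²) DFT to relative error below 1e−6, plus
closed-form checks (sine RMS = A/√2, ZCR of a pure tone = 2f₀/sr).

## Breath/speech separation

Five features discriminate breathing from speech frames: spectral contrast,
roll-off 95%, RMS, bandwidth and mean amplitude. Breathing is broadband and
quiet (low contrast, high roll-off and bandwidth, low RMS/amplitude); voiced
speech is harmonic and loud (the reverse).

*Calibration.* For each feature, the threshold is the midpoint of the breath
and speech class **medians** computed on labelled exemplar frames; the
breath side is whichever side the breath median falls on. Medians rather
than means because the amplitude features are heavy-tailed. A feature whose
class medians coincide is dropped with a warning; fewer than three usable
rules aborts calibration. The pipeline calibrates on the first five
recordings of a cohort by default (`n_exemplars`), mirroring the practice of
hand-labelling a handful of recordings.

*Classification.* A frame is breath when ≥ `min_votes` (default 3 of 5)
rules vote breath. A majority vote is robust to one noisy or excluded
feature and degenerates gracefully; setting `min_votes = 5` gives the
strict all-rules variant.

*Segment assembly.* Frame labels are median-filtered (width 5 frames),
run-length encoded, and cleaned: runs shorter than `min_gap_s` = 0.10 s are
absorbed into their flanking kind first, then remaining runs shorter than
`min_seg_s` = 0.15 s are merged away. The constants suppress single-frame
flicker at the default grid (hop ≈ 23 ms) while preserving the shortest
plausible breath spans (≥ 0.3 s in the generator); all are exposed in the
configuration. Segment boundaries fall on frame-centre times and the final
segment is pinned to the true recording duration, so segment durations sum
exactly to it.

*Breath-cycle statistics.* Mean breath-cycle duration is the mean interval
between successive breath-segment onsets; with fewer than two breath
segments it is NaN (imputed downstream).

## Recording feature vector and labels

23 acoustic features per recording: the mean of each of the nine frame
descriptors over breath-assigned frames and over speech-assigned frames
(18), plus breath count, speech count, total breath duration, total speech
duration, and mean breath-cycle duration. Frames are assigned to the segment
containing their centre. A recording with no detected breath yields NaN for
breath-derived entries; these are median-imputed from training rows only,
and the affected columns are flagged. Sex (0/1), height (cm) and weight (kg)
extend the vector to 26 for the covariate-augmented model variants.

Min-max normalisation is fitted on training rows only (avoiding leakage);
test values are deliberately not clipped and may fall outside [0, 1]; a
constant training column maps to 0.

Labels: lung function is *normal* iff FEV₁% > 80 (the 80.0 boundary is
abnormal). Severity grades default to the standard half-open bands —
normal (> 80], mild [70, 80], moderate [60, 70), moderately severe [50, 60),
severe [35, 50), very severe (< 35) — and the table is fully configurable;
the binary label and the grade agree at every boundary by construction.

## Partitioning

The 70:30 split is performed per recording (not per subject, matching the
reference design of 323 samples split 70:30; a stricter subject-grouped
split is a natural extension). In *balanced* mode rows are stratified over
5-point FEV₁% bins (50, 55], (55, 60], …, (120, 125]; within each bin a
seeded shuffle sends `round(0.7·n)` rows to train (ties toward train;
singleton bins go entirely to train), which bounds the per-bin test fraction
within one sample of 30%. Values outside (50, 125] extend the edge bins with
a warning. *Random* mode is a single global seeded shuffle.

## Models and metrics

Algorithms: ordinary least squares (regression) / logistic regression
(classification, multinomial for severity), random forest, and an RBF-kernel
SVM — all with library-default hyperparameters, seeded where stochastic.
"Linear" in the severity comparison means multinomial logistic regression,
the natural reading of a linear classifier for a multi-class task.

10-fold cross-validation (seeded `KFold` shuffle) estimates training
performance; the reported metrics come from the held-out test split.
Regression reports RMSE and MAE; classification reports accuracy, per-class
precision/recall, macro and weighted F1 (weighted as the headline, matching
common tooling defaults), sensitivity (recall of *abnormal*) and
specificity; the binary task adds ROC points and trapezoidal AUC. SVM ROC
scores are decision-function ranks without probability calibration — AUC is
rank-based, so calibration would not change it. The test suite cross-checks
accuracy against the confusion matrix (1e−12) and trapezoidal AUC against
O(n²) concordant-pair counting (1e−9).

## Synthetic cohort generator

The generator emulates the *shape* of a methacholine-challenge study cohort,
not its phonetics. Defaults: 26 subjects × ~12–13 recordings = 323
recordings of 30 s at 22 050 Hz (PCM16 mono WAV), each with ground-truth
breath/speech interval labels and a manifest (subject, sex, height, weight,
FEV₁%).

*FEV₁% distribution.* Subject baselines are truncated-normal (mean 102,
sd 5); each subject has a maximal challenge-induced drop drawn uniformly on
[0, 68] FEV₁% points, applied along a convex (quadratic) dose ramp peaking
between 50% and 85% of the visit sequence and partially recovering, plus
2-point visit noise, clipped to (50, 125]. These values were calibrated once
so that a 323-recording cohort reproduces three facts of the reference
dataset: modal 5-point bin at 96–105, no recording at or below 50, and
~72% of recordings above the 80% normality cut. Because 26 subject-level
draws dominate, the normal fraction varies across seeds with sd ≈ 0.05; the
distribution tests pin specific seeds.

*Audio.* A recording alternates speech spans (2–5 s) and breath spans
(0.3–1.2 s), starting with speech, until 30 s is reached (the last span may
overshoot). Speech is an additive harmonic source — partials of a
subject-specific f₀ (110–220 Hz) with 1/k amplitude roll-off up to 4 kHz,
random phases, a slow (1.5–3.5 Hz) amplitude envelope, normalised to
RMS 0.2. Breath is white Gaussian noise. The lung-function link enters
through three monotone mechanisms driven by an *effective* FEV₁% = measured
FEV₁% + N(0, `noise_sd` = 2):

- breath RMS = 0.03 · (1 + 0.01 · (100 − FEV₁%)) — louder breathing when
  obstructed, exactly monotone for a fixed noise stream;
- speech-span duration shifted by 0.02 s per FEV₁% point — breath onsets
  come closer together (higher respiratory rate) when obstructed;
- breath-span duration scaled by 0.004 per point — longer breaths when
  obstructed.

Since the acoustics depend on lung function only through the noisy effective
value, ~2 FEV₁% points is the best achievable reconstruction RMSE; the
planted-signal acceptance test requires the full pipeline to reach 6 points,
leaving room for segmentation and estimation error.

*What the generator does not model* — and therefore what passing tests do
not establish about real data: phonetic content and articulation, inter- and
intra-speaker spectral variability beyond f₀, microphone/room acoustics,
background noise, non-respiratory pathology, and any nonlinearity or
saturation of the FEV₁%→acoustics relationship. The generator guarantees the
threshold mechanism has signal to find (class interquartile ranges of the
five discriminative features do not overlap); real recordings may not.

## Design choices where the design was open

- Recording length: 30 s default (configurable); cohort layout
  (recordings per subject) is configurable, not asserted, since only the
  totals (26 subjects, 323 recordings) are fixed.
- The five-threshold combination rule is a 3-of-5 majority vote
  (configurable to all-5); thresholds as midpoints of class medians.
- Per-frame feature computation followed by per-segment averaging (rather
  than computing features on whole concatenated segments) — an
  interpretation; it keeps the frame grid uniform and the features
  oracle-testable.
- Feature schema: the 23 acoustic features are the 2×9 per-kind frame-mean
  features plus five segment statistics, fixed and named in
  `voicelung.dataset.ACOUSTIC_FEATURES` — the package's canonical
  definition.
- Normalisation is fit-on-train (a `normalize-on-all` variant would be a
  one-line change but invites leakage).
- The severity boundary table is config-driven; the default is the standard
  ATS-style banding listed above.

## Problem sizes used in the checks

The test suite scores segmentation on a 50-recording cohort (seed 0) and
signal recovery on twenty 100-recording cohorts (seeds 0–19); the
reproduction script runs the full 26 × 323 design. These sizes keep each
check comfortably inside a desktop run while leaving the statistical
conclusions unchanged — recovery margins are wide (frame accuracy ≈ 0.99
vs the 0.95 requirement, RMSE ≈ 2–3 vs the 6-point bound).

## Known limitations

- Recordings of one subject appear in both train and test (split by
  recording); with only 26 subjects a subject-grouped split would be more
  conservative and is left as a flag-level extension.
- The multi-class task is heavily imbalanced by design (most recordings are
  normal); accuracy there mostly reflects the majority class, which is why
  per-class metrics and F1 are reported alongside.
- The synthetic link is linear and monotone; pipeline performance on it is
  an upper bound, not an estimate, of performance on clinical recordings.
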