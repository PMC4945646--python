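# Methods

`physioad` implements an end-to-end pipeline that classifies TV commercials
as **positive / neutral / negative** in effectiveness from the physiological
response of the people watching them.  Because no public recordings exist for
this paradigm, the package is built around a synthetic-session generator
whose outputs drive — and test — every downstream stage: preprocessing,
feature extraction for four signal families, and a staged, cross-validated
classifier protocol.

## The experimental paradigm being emulated

A session is a ~30-minute documentary into which three blocks of three
commercials are inserted: the first block starts no earlier than minute 7,
and every block is preceded by at least two minutes of documentary that
serves as the neutral EEG baseline.  Nine commercials are shown — four
labeled positive, two neutral, two negative (labels derived from a panel
effectiveness score), plus one unlabeled spot that the final model must
classify.  Presentation order is a seeded permutation drawn **per subject**;
with a single order shared by the whole cohort, position-dependent signal
features (e.g. the tonic skin-conductance drift level at a given minute)
identify the ad and therefore its label, and we measured a null-effects
cohort scoring ~95% "accuracy" through that confound alone.  Independent
per-subject orders remove it (null accuracy returns to chance).

## Synthetic signals

All traces of one subject share the session timeline.  Units and rates:
EEG in µV at 256 Hz (30 channels, 10–20 montage), ECG in mV at 256 Hz, skin
conductance in µS and respiration in arbitrary units at 32 Hz.

* **EEG** — per channel: 1/f background (10 µV SD) plus band-limited
  oscillators (theta 3, alpha 4, beta 2, high-beta 1 µV).  The theta
  oscillator on the twelve frontal channels is scaled by the ad-class gain
  multiplier while an ad is on screen.  Blinks are a Poisson train
  (0.2 Hz) of 400 ms raised-cosine deflections (~100 µV at Fp, halved at F,
  quartered at FC), identical in timing across frontal channels so ICA can
  isolate them as one component.  Optional corrupted channels carry long
  flat runs and heavy-tailed spikes.
* **ECG** — a Gaussian-bump PQRST template placed at cumulative RR times.
  `RR(t) = base·m_class + 25 ms·sin(2π·0.1t) + 15 ms·sin(2π·0.25t) +
  30 ms·m_drift·sin(2π·0.0035t+φ) + N(0, 5 ms)`, base 800 ms.  Class
  multipliers act on the base interval and on the slow-drift amplitude.
  50 Hz interference and baseline wander can be switched on for filter
  tests.
* **GSR** — slow tonic level (2 µS, 10-minute sinusoid plus a small linear
  drift) plus discrete sudomotor responses: a bi-exponential kernel (rise
  0.7 s, decay 3 s, lognormal amplitudes around 0.35 µS) at a Poisson rate
  of 1.5/min during documentary and a class-conditional rate during ads.
* **Respiration** — a frequency-modulated sinusoid around 0.25 Hz.

Every injected event (blink times, true R times, SCR onsets) is kept in a
ledger so detectors are scored against ground truth rather than against
other estimators.

**Effect presets.** `ClassEffects.default()` gives moderate separation on
all channels; `strong()` concentrates well-separated effects on the SCR rate
(12/6/2 per minute for positive/neutral/negative) and the RR drift amplitude
(×3/×1.5/×0.5) while leaving EEG and mean heart rate uninformative — it
isolates the two channels the recovery experiment is about; `null()` removes
all class structure (negative control).  The unlabeled holdout ad responds
with positive-class physiology; its label is withheld from the classifier,
not from the body.

**Missing-data model.** Mirroring recordings lost to corruption, the default
drop model removes EEG from 12 subjects, ECG+respiration from 4 and GSR from
3 (at the emulated cohort size of 47 this leaves 35/43/44).  Simulation
experiments in this package pass `DropModel.none()` so every modality is
present.

**What the generator does not emulate:** volume-conducted source mixing and
realistic scalp topographies, ectopic beats and arrhythmia, motion
artifacts, electrode drift, respiratory sinus arrhythmia coupling into HRV,
or any true psychophysiology.  Passing tests demonstrate that the pipeline
recovers structure *of the kind injected*; they say nothing about effect
sizes in real viewers.

## Preprocessing

* **EEG**: mean subtraction; zero-phase 0.5–40 Hz Butterworth band-pass.
  Channel QC rejects channels flat for >10% of the recording or whose
  non-excess kurtosis is a >3 z outlier **across channels** (plain z, not
  MAD-based: on long recordings the sampling spread of kurtosis is ~0.01,
  so a robust scale would reject every blink-bearing frontal channel —
  blinks are ICA's job, not QC's).  Rejected channels are interpolated from
  the 4 nearest good electrodes (inverse-distance weights, standard 10-20
  coordinates via MNE).  1-s epochs are dropped when any channel's
  intra-epoch kurtosis is a robust-z outlier beyond 8 across that channel's
  epochs — deliberately liberal so gross spikes go but blink epochs remain
  for ICA to learn from (<5% rejected on clean data).  FastICA (30
  components, seeded) is estimated on a FIR-decimated copy of the kept
  epochs (spatial unmixing is sample-rate independent); sklearn's
  "did not converge" tolerance warning is routine on a near-Gaussian
  background subspace and is not treated as failure — only a non-finite
  unmixing aborts (returning the input unchanged with a warning).
  Components are scored as `frontal concentration × (1 + positive excess
  kurtosis) × max/median epoch variance`; a 2-cluster split of log-scores
  flags the upper cluster only when the cluster means are ≥2.5 log units
  apart **and** a flagged component loads frontal electrodes ≥1.5× the
  montage average.  Flagged components are zeroed and the full continuous
  recording is back-projected, preserving the time axis that stimulus
  windows refer to.
* **ECG**: mean subtraction; 0.5 Hz high-pass as a symmetric (linear-phase)
  FIR applied centred, hence zero-phase; 50 Hz notch (Q=30, filtfilt);
  65 Hz Butterworth low-pass (midpoint of the 60–70 Hz range).
* **GSR / respiration**: grayscale morphological opening then closing with
  flat structuring elements of 0.5 s and 0.25 s respectively — shorter than
  the narrowest physiological event each signal carries, so ripple goes and
  peak locations stay.

## Feature extraction

**EEG (98 per subject × ad).** Global Field Power is the printed pairwise
form `GFP = sqrt(ΣᵢΣⱼ(uᵢ−uⱼ)²/Nₑ)` over the 12 frontal electrodes, computed
through the identity `ΣᵢΣⱼ(uᵢ−uⱼ)² = 2Nₑ·Σᵢ(uᵢ−ū)²`; it differs from the
classical cross-electrode SD only by the constant `sqrt(2Nₑ)`, and the
baseline Zscore `(GFP−mean(GFP_B))/sd(GFP_B)` is invariant to that constant.
Bands: delta 1–3, theta 4–7, alpha 8–12, beta 13–24, high-beta 25–40, gamma
25–100 Hz (gamma is truncated in practice by the 40 Hz low-pass; it is
computed, not "fixed").  Per band: mean GFP, mean Zscore, and log of the
mean Zscore (missing when the mean is non-positive) → 18 features.  Welch
band power per frontal electrode with 128-sample rectangular windows (the
plain |FFT|²/N periodogram) at 50% overlap → 72 features.  Eight index
features: time-averaged theta and alpha Zscore; an interest index
(fraction of supra-threshold Zscore peaks whose apex falls inside brand-
exposure windows, threshold 3, missing when no peaks) in theta and beta;
and total/brand peak counts in theta and high-beta.  A peak is one maximal
contiguous excursion at or above threshold, counted once, attributed to a
brand window by its apex time.  Peaks are evaluated per subject so the
features are per-instance; memorization (per-subject GFP normalised to unit
sum, averaged within remember/forget groups) and pleasantness (right-minus-
left frontal GFP, like/dislike groups) remain group-level curves, smoothed
with a cubic smoothing spline whose parameter is chosen by generalized
cross-validation.

**HRV (56).** Pan-Tompkins R detection (5–15 Hz band-pass, derivative,
squaring, 150 ms integration, adaptive dual thresholds with search-back,
200 ms refractory, apex refinement on the band-passed signal) achieves
≥99% sensitivity and precision on clean synthetic ECG at 40–120 bpm.  The
tachogram applies a deterministic artifact rule in place of expert review:
drop intervals outside 300–2000 ms or deviating >20% from the 5-beat local
median.  Time domain (11): max/min/mean/median RR, SDRR, SDARR (SD of
30-s-window mean RR — the conventional 5-minute window would exceed one
commercial; within a 60 s ad this gives two windows), RMSSD, RR50 (|ΔRR| >
50 ms), pRR50, mean and SD of instantaneous HR.  Frequency (14 × 2): band
powers over ULF 0–0.033, VLF 0.033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz
(ULF/VLF are physiologically meaningful only in day-long records but are
retained as features), as peak frequency, absolute, percent and normalised
powers, total power and LF/HF — once by Welch on a 4 Hz cubic-spline
resampled tachogram and once by Lomb-Scargle on the raw uneven samples.
Time-frequency (14): the Welch metrics on 30 s windows at 50% overlap,
averaged; a segment no longer than one window degenerates to the plain
Welch values.  Nonlinear (3): Poincaré SD1/SD2 from population variances of
successive differences, and Sample Entropy (m=2, r=0.2·SD, Chebyshev
distance, both template lengths counted over the same n−m start positions
so a constant series gives exactly 0).  RR is in ms, heart rate in
beats/min; entries that cannot be computed are NaN and the vector length is
always 56.

**GSR (10) / respiration (6).** Extrema come from a sign-change scan with
plateau midpointing and enforced alternation; excursions shallower than
0.05 µS (the conventional SCR amplitude criterion) are pruned for GSR, and
breaths must swing ≥10% of the segment's range.  GSR: mean, variance, SD,
counts of maxima and minima, mean min→max rise (each maximum paired with
the immediately preceding minimum), global max/min/range, and peaks per
second.  Respiration: rate (max-to-max breaths/min), mean level, longest
and shortest inter-breath interval, max and min.

## Evaluation protocol

Instances are (subject, ad) pairs; the unlabeled ad never enters training.
Dataset variants and their dimensionalities: GSR 10, RSP 6, HRV 56,
EEG_GFP-ZSCORE 18, EEG_PSD 72, EEG_IND 8, EEG_ALL 98, GSR+HRV 66,
GSR+HRV+EEG_IND 74, GSR+HRV+EEG_ALL 164.  Combinations keep only instances
present in every constituent family.  Missing entries are mean-imputed,
classes are balanced by SMOTE (synthetic points uniformly placed on
segments to one of 5 same-class nearest neighbours), and columns are
z-scaled (constant columns zeroed with a warning).

**SMOTE order.** The default applies SMOTE to the full table before
cross-validation, replicating the published order.  This leaks synthetic
copies of test instances into training folds: on a null-effects cohort we
measure ~73% macro accuracy with the default order versus ~34% (chance)
with the optional leak-free mode (`smote_in_folds=True`).  Experiments that
assert chance-level behaviour therefore use the leak-free mode; headline
recovery numbers use the default order and are read accordingly.

**Classifiers.** Random Forest with 100 trees, unlimited depth, all
features eligible at each split; AdaBoost with 10 reweighting iterations
(the Weka-style weight-pruning threshold of 100 keeps every instance);
one-against-all for the multiclass meta-scheme; bagging with 10 bags.
Cascades: RF, MCC+BAG+RF, ASC+RF (wrapper attribute selection inside the
classifier), AB+RF, MCC+AB+RF.  Baselines: SVM (RBF), multilayer
perceptron, logistic regression, Gaussian naive Bayes, 1-nearest-neighbour
(brute force), Zero Rule (majority class; exactly (100, 0, 0) per class and
33.33% macro on any balanced 3-class table), One Rule as a decision stump,
and two CART stand-ins: a depth-4 tree for the decision-table baseline and
an unlimited tree for the Hoeffding tree (its large-sample batch limit).

**Cross-validation and scoring.** Stratified 10-fold (fold class counts
within one instance of proportionality); per-class accuracy is class recall
aggregated over folds; the reported "average" is the arithmetic (macro)
mean of the three per-class accuracies.

**Wrapper selection.** Greedy forward search scored by the internal
stratified 5-fold accuracy of the base classifier, stopping when no
extension improves the best score (patience 1); deterministic under the
seed.  `ASC+RF` embeds the same search inside `fit`, so cross-validating it
re-selects per fold.

**Protocol rounds.** Round 1 scores every individual variant; variants
whose best average is ≥75% advance.  Round 2 scores GSR+HRV-anchored
combinations of winners.  Round 3 re-scores GSR and the combinations
restricted to wrapper-selected attributes under the extended cascade set
(adding AB+RF and MCC+AB+RF).  The best round-3 cell is trained on the full
(selected, standardised) table and predicts the held-out ad; the report
carries per-instance predictions, vote shares and the majority vote (ties
break alphabetically).

## Problem sizes and numerical choices

Simulation studies use the compact session layout (~20.5 min: 420 s opening
documentary, 60 s ads, 120 s inter-block documentary, 30 s tail) — the
shortest layout satisfying the structural invariants — chosen so a
40-subject recovery experiment with wrapper selection completes in a few
minutes on one CPU.  Ad duration defaults to 60 s: with 30 s spots the
30-s-window SDARR feature degenerates to a single window inside an ad.
Filters are Butterworth order 4 applied forward-backward (zero-phase)
except the ECG high-pass (symmetric FIR, centred) and the notch; all event
detectors are therefore lag-free, which the tests check by cross-
correlation.  Ties and degenerate inputs: zero-variance kurtosis reports a
degenerate channel rather than raising; II with no peaks, log of a
non-positive mean Zscore, LF/HF with zero HF power and interval features of
a breathless segment are NaN, propagated (never shrinking a vector) and
mean-imputed only at the classification stage.

## Known limitations

Accuracies obtained on synthetic cohorts depend on the configured effect
sizes and are not comparable to values measured on human recordings.  The
blink model is a single stereotyped template; ICA separation is easier than
on real EEG (no saccades, no muscle).  The wrapper search is greedy and can
miss interacting feature pairs.  SMOTE-before-CV optimism is inherent to
the replicated protocol order and is quantified, not removed, here.
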