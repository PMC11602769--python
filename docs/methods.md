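# Methods

`wardsense` re-implements, as a tested pipeline on synthetic data, a
wearable-based analysis for predicting clinician-rated symptom scores
in acute psychiatric inpatients. This note documents the models the
package implements, the assumptions behind the synthetic cohort
generator, the numerical choices, and what the test suite does and does
not demonstrate.

## The prediction problem

Inpatients wear a wrist device recording heart rate, 3-axis
acceleration and indoor location; clinicians rate four symptom scales —
BPRS (psychotic/general, 0–108), HAM-A (anxiety, 0–56), MADRS
(depression, 0–60), YMRS (mania, 0–60) — at admission, weekly
thereafter, and after clinical events. Two tasks are defined per scale:

* **Deterioration** (within-subject): did the scale total strictly
  increase versus the participant's previous assessment? The first
  assessment has no label; ties are negative.
* **Score** (between-subject): regress the absolute scale total.

Each task is solved **single** (one model per scale) and **multi** (one
multitask model with four heads and a fully shared backbone), giving
the four configurations Single/Multi × Deterioration/Score.

## Feature engineering

Raw minute-cadence streams are summarized per clock hour into 29
features: eight window statistics (first, last, mean, median, max, min,
sample SD, number of unique values) for total acceleration
√(ax²+ay²+az²) and for heart rate; cumulative calories, sleep index,
steps and distance; location variance (var x + var y of the position
fixes); the fraction of observed time in each semantic zone (room,
hallway, other, no signal); and Shannon location entropy, raw and
normalized by ln 4, over calendar days and over 8-hour blocks
delimited at 00:00/08:00/16:00, broadcast to the hours each period
covers. Age (divided by 100) and sex (0 = male, 1 = female) are
appended downstream as constant columns, for 31 input features.

Choices worth stating:

* Windows are half-open hourly bins aligned to clock hours, stride one
  hour (one row per hour is what a 672-row, 4-week input implies).
* The SD uses the n−1 denominator; a one-sample window leaves it
  missing (later imputed).
* "Number of unique values" is counted after rounding to device
  resolution (1 bpm; 0.01 g): float-level uniqueness is degenerate.
* The sleep index maps cumulative daily flagged sleep D (hours) to
  30 + 70·(D − 2.25)/5.25, clamped to [30, 100]; only the endpoints of
  this map are anchored by the device's documentation, linearity in
  between is our choice. The daily score is prorated uniformly across
  the day's 24 hourly rows, so the day's cumulative equals the score.
* Semantic location enters as four time-fraction columns (not the
  single modal zone): the per-zone features the importance analysis
  names require fractions, and the registry then totals exactly 29.
* Entropy uses the fixed four-zone alphabet including "no signal", so
  periods are comparable; bounds are [0, ln 4].

**Imputation.** Missing cells (device-off episodes, empty periods) are
completed by soft-impute: iterate {fill missing cells with the current
low-rank estimate; SVD; soft-threshold singular values by λ; truncate
to rank ≤ 10} until the relative Frobenius change is below 1e-5 (at
most 100 iterations), with λ = 0.1·σ₁ of the zero-filled matrix.
Columns are standardized before and de-standardized after; observed
cells are restored exactly; imputed cells of bounded columns
(fractions, entropies, non-negatives) are clipped to their valid
range. Participants whose raw stream is more than 50% missing
(strictly) are excluded before modelling.

**Examples.** Each assessment is linked to the 672 hours ending at its
hour (timestamp floored); older rows are dropped, shorter histories are
zero-padded on the oldest side. Standardization (per-feature z-scoring)
is fit on the training examples' real rows only and applied before
padding is inserted, so padded rows are exactly zero — a neutral
input. Participants with fewer than two assessments are dropped.
Recruitment before the cutoff date (2024-05-01 by default) assigns a
participant's examples to the cross-validation split, later recruits to
the temporal external-validation split; no participant straddles the
split.

## Model

All configurations share one backbone: two temporal 1D convolution
blocks over the 672-hour axis with the 31 features as input channels
(channels 32 then 64, kernel 5, stride 1, ReLU, max-pool 4), a
single-layer GRU (hidden 64) whose last hidden state passes through
dropout (0.2) and a 32-unit ReLU layer, then one scalar head per
target scale — sigmoid for deterioration, linear for score. Pooling by
4 per block (672 → 168 → 42 GRU steps) rather than 2 was chosen
because a 42-step recurrence retains 4-week context much better than a
168-step one and trains about three times faster; at 42 steps each GRU
step spans 16 hours of input.

The network, its backpropagation (including BPTT through the GRU) and
the Adam optimizer are implemented in numpy inside the package
(`wardsense.nn`); the analytic gradients are verified against central
finite differences in the test suite. Deterioration heads minimize
masked binary cross-entropy (undefined first-assessment labels are
masked out); score heads minimize MSE on min-max-scaled scores so the
four losses are commensurate; multi models sum the head losses with
configurable weights (default 1 each). Training uses Adam (lr 1e-3),
batch 16, up to 80 epochs with early stopping (patience 12) on a
participant-grouped 15% validation split, and never before epoch 30 —
with only a handful of validation participants the validation loss is
noisy early on and stops training far too soon otherwise. The best
validation state is restored. Everything is deterministic given the
training seed.

Hyperparameter search, when enabled, samples uniformly from
lr ∈ log-uniform[1e-4, 1e-2], GRU hidden ∈ {32, 64, 128},
kernel ∈ {3, 5, 7}, dropout ∈ [0, 0.5], batch ∈ {16, 32}, scoring each
draw by participant-grouped k-fold CV (mean AUC or R²).

## Evaluation design

Cross-validation is 5-fold and grouped by participant — all of a
participant's assessments share a fold; example-level folding would
leak within-subject information. Deterioration models report accuracy
at threshold 0.5 and the tie-corrected rank (Mann-Whitney) AUC, with
per-fold ROC curves pooled vertically: mean TPR ± 1 SD at 101 evenly
spaced FPR points, linear interpolation within folds. Score models
report R² and NRMSE = RMSE divided by the instrument's theoretical
range (stable across folds, unlike the observed range). "Overall"
values pool every head's (prediction, truth) pairs — min-max
normalized per scale for the score task — into one computation.
Permutation importance permutes one feature's entire 672-row column
block across external examples (5 repeats) and records the AUC or R²
drop, converted to ranks 1–31. The ward-distribution view embeds
sampled hourly 31-feature rows with t-SNE (perplexity 30, PCA
initialization, 1000 iterations, fixed seed).

## Synthetic cohort generator

No public data exist for this setting, so the generator is a
first-class, tested component that plants known structure:

* **Latent severity.** Per scale, an hourly path: initial severity
  (normal marginals roughly matching acute-ward admission levels,
  shifted by age/sex effects) + improvement drift (−0.4 points/day) +
  AR(1) noise (φ = 0.98/hour, exchangeable cross-scale innovation
  correlation 0.35) + compound-Poisson relapse jumps (0.05/day, sizes
  concentrated at ≥ half the per-scale mean so relapses are
  clinically meaningful steps), clipped to the scale range. Jump events
  are shared across scales with independent per-scale magnitudes.
* **Couplings.** Normalized severity (score/range) shifts behaviour
  through a coupling matrix in which each scale loads a distinct
  channel combination — psychotic symptoms mainly raise zone-switching
  (hence location entropy), anxiety raises resting heart rate,
  depression lowers daytime activity and adds hypersomnia, mania cuts
  sleep and raises activity. An early draft loaded all scales on the
  same channels with similar signs; the four severities were then not
  jointly identifiable from the four behavioural channels and no
  method, linear or neural, could separate them. Identifiability of
  the planted effect is a design requirement of the generator.
* **Emission.** Minute-cadence heart rate = ward baseline + circadian
  sinusoid + activity term + severity shift − sleep dip + noise;
  acceleration components are zero-mean with SD proportional to the
  momentary activity level (gravity on z); location follows a
  per-minute Markov chain over the ward's zones with a
  severity-coupled switch rate plus transient no-signal dropouts;
  steps/calories/distance derive from the activity profile; one sleep
  interval per night with severity-coupled duration sets the sleep
  flag. Nightly sleep onset ~23:00 ± 30 min.
* **Missingness.** Device-off episodes follow an alternating renewal
  process: exponential off-episodes (mean 45 min) and on-periods sized
  so the long-run off fraction matches the ward's rate; all channels
  blank during an episode; the realized fraction is recorded and
  drives the 50% exclusion rule. An informative-missingness variant
  (removal rate rising with severity) sits behind a flag and is off by
  default.
* **Schedule.** Baseline rating at admission, weekly thereafter;
  relapse jumps above 5 points trigger an extra rating the following
  day with probability 0.5. Observed totals are latent severity plus
  rater noise (SD 2), rounded and clipped. At the defaults roughly a
  quarter to a third of labelled assessments are deteriorations,
  matching the range reported for real acute-ward cohorts.
* **Wards.** Four ward profiles across three notional hospitals differ
  in heart-rate baseline (66–78 bpm), activity scale (0.85–1.15),
  missingness (10–18%) and recruitment window; recruitment dates drawn
  within the window enable the temporal split (cutoff 2024-05-01 →
  roughly a quarter of participants external).

Two presets define the signal-recovery study conditions:
`CohortConfig.strong_signal(40)` (fixed 28-day stays, tripled
couplings, doubled jump sizes, doubled demographic effects, low
sensor/rater/process noise, homogeneous wards — ward-level shift is a
noise source for this purpose) and `CohortConfig.null_signal(40)`,
identical but with all couplings zero. Under the former the Multi
models recover the planted association externally (pooled R² ≥ 0.5,
pooled AUC ≥ 0.7 at the tested seed; across other seeds R² ≈ 0.5–0.7,
AUC ≈ 0.68–0.9); under the latter the score R² is ≤ 0 and the AUC sits
near chance (≈ 0.55–0.65 — slightly above 0.5 because assessment
timing and padding carry weak incidental information about
deterioration probability even without any sensor coupling).

**What the synthetic data does not emulate:** diagnosis-specific
sensor signatures (couplings are generic severity effects), PPG
waveform artefacts, real floorplans or step-detection physics, rater
drift, and informative missingness by default. Passing the recovery
tests therefore shows the pipeline can extract a planted
sensor–symptom association of realistic shape and size at n = 40 — it
does not certify clinical performance on real wards, which in the
source setting also faced substantial between-ward distribution shift.

## Degenerate inputs and tie-breaks

All-missing windows yield missing statistics (imputed later); empty
entropy periods are missing; a fully missing feature column is an
error naming the column; zero-variance truth leaves R² undefined
(flagged) rather than ±∞; single-class label sets leave AUC undefined
(flagged) and training emits a warning; equal probabilities at the 0.5
threshold count as positive predictions; importance ties are ranked
stably in registry order.

## Problem sizes

The default test and acceptance runs use 6–40 participants with 8- to
28-day stays. These sizes were chosen so the complete study — two
40-participant cohorts, feature engineering, and four model fits —
runs in a few minutes on one CPU core while keeping ≥ 30 external
examples for the validation metrics.
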