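# wardsense

Wearable-sensor symptom prediction for acute psychiatric wards: a
tested, end-to-end pipeline from raw wrist-device streams (heart rate,
3-axis acceleration, indoor location, device cumulatives) to
deep-learning predictions of clinician-rated symptom scales, together
with a synthetic multi-ward cohort simulator that makes every stage
verifiable without access to protected clinical data.

It is written for methods researchers in digital phenotyping and
clinical prediction who want a reproducible reference implementation
of this study design — the feature engineering, the multitask sequence
model, and the validation protocol — with planted-signal recovery
tests in place of an irreproducible clinical dataset.

## What it implements

Inpatients wear a wrist device throughout admission; raters score four
scales — BPRS, HAM-A, MADRS, YMRS — at baseline, weekly, and after
clinical events. For each assessment the model input is the preceding
4 weeks of hourly sensor features, **X ∈ ℝ^(672×31)**: 29 engineered
sensor features (window statistics of total acceleration
√(a_x²+a_y²+a_z²) and heart rate; cumulative calories, sleep index,
steps, distance; location variance, per-zone time fractions, and
location entropy H = −Σ_z p_z ln p_z over daily and 8-hour periods)
plus age and sex. Missing sensor data are completed by soft-impute
(iterative soft-thresholded SVD); participants over 50% missing are
excluded; short histories are zero-padded.

Two tasks per scale, each in a single-scale and a multitask (MTL)
variant, give four configurations — Single/Multi ×
Deterioration/Score:

* **Deterioration** — P(y_i(s) > y_{i−1}(s)), a within-subject
  classification of strict score increase versus the previous
  assessment (evaluated by accuracy, tie-corrected AUC, and
  vertically pooled ROC curves);
* **Score** — ŷ(s) ≈ y(s), between-subject regression of the absolute
  total (evaluated by R² and NRMSE = RMSE / score range).

All configurations share one backbone — temporal 1D convolutions over
the 672-hour axis, a GRU whose last hidden state feeds a fully
connected layer, then one output head per scale — implemented in numpy
with gradient-checked backpropagation. Validation follows the study
design: participant-grouped 5-fold cross-validation on participants
recruited before a cutoff date, temporal external validation on later
recruits, random-search hyperparameter tuning, permutation feature
importance on the external set, and a t-SNE view of the feature
distribution by ward.

Because the clinical cohort is protected, the package ships a
first-class synthetic generator (`wardsense.cohort`): latent AR(1)
severity trajectories with improvement drift and compound-Poisson
relapse jumps, coupled onto sleep, activity, location switching and
resting heart rate; circadian structure; ward-level heterogeneity;
device-removal missingness; and the weekly + event-triggered
assessment schedule. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
import wardsense as ws

cfg = ws.CohortConfig.strong_signal(n_participants=40, seed=7)
bundle = ws.generate_cohort(cfg)                 # streams + ratings + metadata
series, excluded = ws.featurize_cohort(bundle)   # hourly 29-feature series
dataset = ws.build_dataset(bundle, series)       # 672x31 examples, cv/external
print(f"{len(dataset)} examples: {len(dataset.split('cv'))} cross-validation, "
      f"{len(dataset.split('external'))} external")

model = ws.SymptomSequenceModel(dataset.split("cv"), mode="multi", task="score")
res = model.fit(ws.TrainConfig(seed=0))
print(res.summary())

m = ws.pooled_score_metrics(res, dataset.split("external"))
print(f"external pooled R2 = {m['r2']:.3f}, NRMSE = {m['nrmse']:.3f}")
```

prints

```
220 examples: 179 cross-validation, 41 external
Symptom sequence model — Multi-Score
====================================
heads             : BPRS, HAMA, MADRS, YMRS
parameters        : 42,340
training examples : 179
epochs run        : 76
best epoch        : 62
final train loss  : 0.0201
best val loss     : 0.0376
learning rate     : 0.001
batch size        : 16
architecture      : conv[32, 64] k5 pool4 -> GRU(64) -> FC(32)

external pooled R2 = 0.511, NRMSE = 0.123
```

The cohort plants strong severity→behaviour couplings, so the
multitask score model explains about half the between-subject variance
of the four scale totals on participants it has never seen, recruited
after the temporal cutoff; on the zero-coupling twin cohort
(`CohortConfig.null_signal`) the same pipeline finds nothing (external
R² ≤ 0, AUC near chance) — the recovery is signal, not leakage.

The same pipeline is scriptable from the shell:

```bash
wardsense simulate --config cohort.yaml --out cohort/ --seed 7
wardsense featurize --in cohort/ --out features/
wardsense evaluate --cohort cohort/ --config exp.yaml --out results/ --seed 7
wardsense run-all --config smoke.yaml --out run/ --seed 7   # all stages
```

Every run writes a `manifest.json` (config hash, per-stage seeds,
package version, timings, output checksums).

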