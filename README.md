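# ecgscar

Explainable detection and regional localization of left-ventricular (LV)
scar from 12-lead ECGs, for researchers working on ECG-based phenotyping of
hypertrophic cardiomyopathy and related myopathies where MRI late gadolinium
enhancement — the reference marker of replacement fibrosis — is costly or
unavailable for longitudinal monitoring.

## What it does

Given fiducial-annotated 12-lead ECGs (QRS onset/offset, Q/R/S peaks,
T onset/peak/offset, next P onset, produced by an upstream delineator), the
pipeline:

1. **Extracts features** — 23 depolarization/repolarization descriptors per
   lead (amplitudes, durations, slopes, fragmentation, energy
   ∫(v−b)²dt and signed area ∫(v−b)dt of QRS and T, ST/TP descriptors),
   averaged over beats and concatenated lead-major into a vector
   *V* ∈ ℝ²⁷⁶ (12 × 23).
2. **Adjusts for confounders** — each feature is residualized on LV mass
   index, age and sex by OLS during *training only*; inference uses raw
   features.
3. **Partitions patients** — a Dirichlet-process Gaussian mixture clusters
   patients by ECG similarity; clusters where one class outnumbers the
   other by a dominance ratio (2.0, halved each iteration) are pooled into
   merged groups. The recursion provably stops within two iterations and
   yields at most two groups.
4. **Classifies per group and region** — an encoder f is pretrained with
   SCARF-style random feature corruption (60% of coordinates resampled from
   the empirical training marginals) under an InfoNCE contrastive loss, then
   a head h is attached and both are fine-tuned on weighted cross-entropy.
   Regional probabilities (basal, mid, apical) combine into a global call by
   OR.
5. **Explains** — Kernel SHAP attributes each prediction to the 276
   features (φ-values satisfy base + Σφ = f(x) exactly); cohort summaries
   report mean |φ| per ECG component × lead and the frequency with which
   each feature ranks in the top 20% of |φ|.

Because clinical cohorts cannot be shipped, the package includes a
first-class synthetic generator: Gaussian-wave beats with closed-form
feature values (the extractor's oracle), and feature-space cohorts with
planted patient clusters, cluster-dependent scar prevalence and signature
polarity, and confounder couplings (LVMI↔V4 QRS energy r≈0.6, LVMI↔scar
burden r≈0.4). See `docs/methods.md` for the full model.

## Worked example

```python
from ecgscar import CohortConfig, PipelineConfig, generate_cohort, run_train
from ecgscar.pipeline import explain_batch, split_patients
from ecgscar.explain import top_feature_frequency

cfg = PipelineConfig().with_seed(11)
table, truth = generate_cohort(cfg.cohort)        # 600 patients, ~1800 ECGs
pipe, report = run_train(table, cfg)              # train + 20% patient hold-out
print(report.to_frame()[["ppv", "sensitivity", "specificity", "f1"]].round(2))
```

```
         ppv  sensitivity  specificity    f1
basal   0.83         0.86         0.84  0.84
mid     0.89         0.83         0.90  0.86
apical  0.91         0.89         0.92  0.90
global  0.97         0.86         0.95  0.91
```

Each row is patient-level held-out performance for one LV region; `global`
is the OR rule (scar anywhere). The planted regional signatures are
recoverable from the explanations — for apical scar the top-20% Shapley
selection frequencies are led by chest-lead T-wave features, the signature
the generator planted:

```python
_, test_df = split_patients(table, cfg.train.test_fraction, cfg.train.seed)
exps = explain_batch(pipe, test_df, "apical", max_ecgs=25, seed=11)
print(top_feature_frequency(exps).sort_values(ascending=False).head(5).round(2))
```

```
V3_t_amplitude    0.72
V6_t_amplitude    0.72
V4_t_amplitude    0.68
V5_t_amplitude    0.64
V5_t_inversion    0.56
```

i.e. T-wave amplitude/inversion in V3–V6 appeared among the 56 most
influential features in 56–72% of apical predictions.

## Command line

```bash
ecgscar simulate --seed 4 --out sim/                 # synthetic cohort CSV
ecgscar extract  --annotations ecg.json --out v.csv  # 276-dim vector from waveforms
ecgscar train    --features sim/cohort.csv --seed 4 --out model/
ecgscar predict  --model model/model.pkl --features sim/cohort.csv --out preds.csv
ecgscar explain  --model model/model.pkl --features new.csv --region apical --out expl/
ecgscar evaluate --features sim/cohort.csv --runs 2 --folds 5 --out cv.csv
```

All verbs accept `--config file.yaml` (schema-validated; unknown keys are
rejected) and `--seed`.

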