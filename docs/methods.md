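# Methods

`ecgscar` predicts the presence of left-ventricular (LV) scar in the basal,
mid, and apical thirds of the LV from fiducial-annotated 12-lead ECGs, and
explains every prediction with per-feature Shapley values.  This note
documents the model, its assumptions, the tunable parameters, the synthetic
cohort the test suite runs on, and the numerical choices made where the
design was open.

## 1. Feature extraction

Each beat of each lead is reduced to 23 features of ventricular
depolarization and repolarization; per-beat values are averaged
arithmetically over the beats of a lead and the 12 per-lead vectors are
concatenated lead-major (I, II, III, aVR, aVL, aVF, V1–V6) into a
276-dimensional ECG vector.

The registry, in fixed order:

| # | feature | unit | definition |
|---|---------|------|------------|
| 1–3 | Q/R/S amplitude | mV | sample at the annotated peak minus baseline; an absent Q or S wave contributes 0 |
| 4 | QRS duration | s | offset − onset |
| 5 | QRS non-terminal duration | s | onset → R peak (intrinsicoid deflection) |
| 6 | QRS terminal duration | s | R peak → offset |
| 7–8 | R up/downstroke slope | mV/s | least-squares line fit over onset→R peak / R peak→offset |
| 9 | QRS fragmentation | count | local extrema strictly inside the QRS beyond the annotated Q/R/S deflections, with prominence ≥ 0.05·\|R amplitude\| |
| 10 | QRS energy | mV²·s | ∫(v−baseline)² dt over the QRS window, trapezoid rule |
| 11 | QRS area | mV·s | signed ∫(v−baseline) dt (so "less negative QRS area" is expressible) |
| 12–14 | ST duration / deviation / slope | s, mV, mV/s | deviation sampled at the segment midpoint; slope fit over the whole segment |
| 15–21 | T amplitude, duration, inversion sign, up/downslope, energy, area | — | inversion is sign(T amplitude) in {−1, 0, +1}, with amplitudes below 1 µV counted as absent (sign 0) |
| 22–23 | TP slope / duration | mV/s, s | — |

Conventions: indices are 0-based; segments are half-open `[onset, offset)`
for membership and duration, while windowed numerics (slopes, integrals) use
the closed index range so adjacent segments share their boundary sample as a
trapezoid endpoint.  The per-beat baseline is the median of the TP segment.
Least-squares slopes (not two-point differences) are used for robustness to
single-sample noise.  Energies and areas are computed at the native sampling
rate; on smooth beats the composite trapezoid rule is effectively
superconvergent because the integrand's derivative nearly vanishes at the
3-sigma wave-support edges.

Beat detection and delineation are out of scope: fiducials (QRS
onset/offset, Q/R/S peaks, T onset/peak/offset, next P onset) are consumed
as annotations, via a JSON schema with inline or CSV-referenced waveforms.
Compound clinical scores (e.g. Selvester) are deliberately excluded in
favour of basic, interpretable measurements.

## 2. Confounder adjustment

During training only, each feature is regressed by OLS on LV mass index
(g/m²), age (years) and sex (0/1), and replaced by its residual re-centered
at the training mean — the residual-plus-mean form keeps adjusted features
on their physical scales.  At inference the adjustment is an exact identity:
deployed predictions use raw feature values.  Training on adjusted features
while predicting on raw ones is a deliberate asymmetry of the procedure (a
train/test distribution mismatch accepted by design); it is exposed as a
config switch (`adjust_at_inference`, default off).  No interactions, no
regularization (n ≫ 4 per regression); a rank-deficient design falls back to
the pseudoinverse with a warning.

## 3. Patient partitioning

Patients (represented by the mean of their ECG-row vectors) are z-scored
per feature and clustered with a truncated variational Dirichlet-process
Gaussian mixture (diagonal covariance, 20-component truncation).  A cluster
is *dominated* when one class's population is at least `ratio` times the
other's (multiplicative form, no division; empty clusters are vacuously
dominated).  Iteration k uses `ratio = 2.0 · 0.5^k`: dominated clusters are
pooled into that iteration's merged group, undominated patients carry over.
Once the ratio reaches 1 every cluster is dominated, so the recursion always
stops within two iterations and produces at most two merged groups — the
structure the procedure is designed to converge to.  All dominated clusters
of an iteration pool into a single merged group (the alternative
scar-pool/no-scar-pool policy is available as `merge_policy="by_class"`).

Numerical choices that matter:

* **PCA before the mixture.** The variational objective pays a
  per-component prior cost that scales with dimension; in 276 raw
  dimensions it cannot detect cluster separations below roughly 12
  within-cluster SDs.  Clustering therefore runs on the top 20 principal
  components, where between-cluster variance concentrates; with this
  projection, separations of ~5 SD and up are recovered reliably.
* **Mean-precision prior 10.** Shrinks weakly supported component means
  toward the data mean so that i.i.d. noise is not carved into spurious
  clusters, while well-separated blobs still split cleanly.
* Clusters smaller than `min_cluster_size = 5` are dissolved into the
  nearest surviving cluster.
* **Routing.** A new ECG is assigned to the merged group owning the nearest
  *constituent-cluster* centroid (Euclidean distance in the z-scored
  space; ties break toward the lowest group index).  A merged group that
  pooled several distant clusters is multi-modal, so its own mean can lie
  in empty space — routing through the stored cluster centroids avoids
  that failure mode.
* `no_partitioning` places everyone in one group (used by the ablation).

## 4. Per-group classifiers

For each (region, merged group) an encoder is pretrained with random
feature corruption: 60% of the coordinates (`round(0.6·276) = 166`) are
resampled from the empirical training marginals (a uniform-over-[min, max]
variant is available), and an InfoNCE objective with cosine similarity and
temperature 1.0 pulls each row's embedding toward its own corrupted view
against in-batch negatives.  A fully connected head is then attached and
encoder + head are jointly fine-tuned on inverse-frequency-weighted
cross-entropy (an encoder-freeze option exists).  Groups whose training
labels are single-class get a constant-probability fallback.

Defaults: encoder 276→128→128→32, head 32→32→1, Adam 1e-3, batch 128,
20 pretraining and 15 fine-tuning epochs.  These widths and budgets train
each model in seconds on one CPU core; the short fine-tuning budget is the
setting a practitioner would select for the grouped pipeline, whose
per-group problems converge quickly, and the same budget is reused verbatim
by the ablation arms.  An optional k-fold cross-validation grid
(`cv_grid` over learning rate, embedding width, fine-tune epochs) selects
hyperparameters per group when enabled; it is off by default to keep the
default run time small.  All randomness (initialization, batching,
corruption) flows from explicit seeds; training is bit-reproducible on the
same platform.

Regional probabilities are thresholded at 0.5 (a probability exactly at the
threshold classifies positive) and combined into the global scar call by
OR: global = basal ∨ mid ∨ apical.

## 5. Explanations

Kernel SHAP estimates per-feature Shapley values by weighted least squares
over feature coalitions; a coalition keeps the explained ECG's values on
its members and averages the model output over background substitutions for
the rest.  When all `2^d − 2` proper coalitions fit in the budget they are
enumerated with exact Shapley-kernel weights (the solution then equals exact
Shapley values); otherwise coalition sizes are sampled from the kernel
distribution with unit regression weights (unbiased importance sampling).
The additivity constraint — base value plus the sum of attributions equals
the model output — is enforced exactly by variable elimination.  The
background is the training matrix of the routed group, subsampled to 30
rows by default; explanations are computed per region against that region's
routed group model.

Two cohort-level summaries: mean |φ| per (ECG component, lead) — components
Q, QRS, ST, T, TP partition the registry — and the fraction of predictions
in which each feature ranks in the top 20% by |φ| (⌈0.2·276⌉ = 56 features
per prediction; ties break by registry index).  Magnitude is used for
ranking because importance is the standard reading; signed summaries are
available via a flag.  Welch's unequal-variance t-test compares raw feature
values between scar and no-scar groups; a class with fewer than two
observations yields NaN.

## 6. The synthetic cohort

Clinical ECG/MRI cohorts cannot be shipped, so the test bed is a generator
with fully known ground truth, at two levels.

**Single beats** are sums of Gaussian waves (Q, R, S, T) on a piecewise
smooth baseline (sigmoid-ramped ST plateau, softplus-kneed TP drift), with
fiducials placed at the known 3-sigma wave supports.  Because the
continuous model is known, every feature has an analytic value — durations
from the fiducials, amplitudes from the model at the landmark times,
energies/areas by 16× oversampled quadrature, slopes as the model's
least-squares fit on the native window grid, fragmentation by a dense
extrema scan with a swing-based prominence filter — and the extractor is
required to reproduce all 23 to 1e-3 relative error on random beats.

**Cohorts** are generated directly in the 276-dimensional feature space,
one row per ECG:

* Patients belong to latent clusters (default 3, mixing weights
  0.25/0.25/0.50) whose means are separated by 7 within-cluster SDs —
  heterogeneous ECG phenotypes.  Patient vectors add unit within-cluster
  noise; each patient contributes `clip(round(N(3, 2)), 1, ∞)` ECG rows with
  0.3-SD row-level noise.
* Scar prevalence is cluster-dependent: the cohort-level targets (0.40 /
  0.38 / 0.36 for basal/mid/apical) are shifted per cluster by
  (+0.35, −0.25, 0.0), yielding a scar-enriched cluster, a scar-depleted
  cluster, and a balanced one.  The enriched and depleted clusters are
  class-dominated at ratio 2 and pool in the first recursion iteration; the
  balanced cluster pools in the second — reproducing the two-iteration /
  two-merged-group structure the partitioning stage is designed around.
  Regional labels share a per-patient scar-burden latent (coupling 0.8), so
  regional scars co-occur realistically.
* Regional scar signatures shift specific (lead, feature) columns of
  scar-positive patients: deeper Q (−2 SD) in aVR/I/V1 plus longer
  intrinsicoid deflection for basal scar; lateral T-amplitude loss
  (V5/V6/aVL, reciprocal aVR gain) for mid scar; T inversion across V2–V6
  with a more positive QRS area for apical scar.  Magnitudes (1.5–2 SD) are
  idealized so planted signals are unambiguously recoverable; they are
  configuration, not clinical estimates.  The effect *sign* is modulated by
  cluster (+1, +1, −1 by default with modulation 1.0): the same scar
  presents with reversed polarity in the balanced phenotype.  With the
  default mixing weights the pooled scar-vs-no-scar marginal shift of the
  signature columns roughly cancels, so a model trained without
  partitioning must learn a phenotype × signature interaction — the regime
  in which pooled learning genuinely underperforms grouped learning.
* Confounders: LVMI is log-normal (median 95 g/m², log-SD 0.25) and coupled
  through a Gaussian copula to the V4 QRS-energy column (target Pearson
  r = 0.6) and to the scar-burden fraction (target r = 0.4).  The latent
  correlations are de-attenuated analytically for the log-normal marginal,
  the probit burden transform and the ECG-level noise, so the *empirical* r
  on the generated table lands near the targets; the V4 energy column and
  the derived T-inversion indicator columns carry no cluster offset.

What the generator does **not** emulate: real waveform morphology
(waveform-level and cohort-level generation are separate), wall-level scar
anatomy, arrhythmias, paced/LBBB morphologies, segmentation errors in the
upstream delineation, non-Gaussian feature distributions, and
center-to-center distribution shift.  Passing tests therefore demonstrate
that the pipeline's machinery recovers the structure it assumes —
cluster-conditional signatures, confounder couplings, dominance structure —
not that it would reach any particular performance on clinical data.

## 7. Study sizes and experiment design in the test suite

Desk-scale sizes keep the full suite and the acceptance script each within
a few minutes on one CPU: the default cohort has 600 patients (~1,800
ECGs), end-to-end experiments use three fixed seeds, explanation summaries
use 25–30 held-out ECGs per region with 600 sampled coalitions against a
30-row background, and the repeated cross-validation helper defaults to
2 runs × 5 folds.  Evaluation is at the patient level (mean probability
over a patient's ECGs, then threshold), with Wilson 95% intervals around
accuracy; PPV/Se/Sp/F1 come from the standard confusion-count formulas and
0/0 ratios are reported as NaN, never 0.

The ablation experiment (full vs. no-self-supervised vs. no-partitioning)
compares means over the three seeds under the unmodified default
configuration.  Two behaviours are worth knowing: per-seed the two ablation
arms can swap within noise even when the means are ordered; and in
label-scarce regimes (10–25% of labels visible to fine-tuning) removing
self-supervision costs more than removing partitioning, reversing the
middle of the ordering — partitioning's value here comes from sparing the
models the phenotype-interaction problem, and with abundant capacity, data
and training time a pooled network can eventually learn that interaction
too.

## 8. Known limitations

* The merged-group count and the ablation ordering are properties of the
  synthetic study conditions; other generator settings (e.g. uniform
  cluster prevalence) legitimately produce one merged group or a pooled
  model that matches the full pipeline.
* Kernel SHAP explains the routed group's model only; attributions carry no
  uncertainty estimate, and feature interactions are not decomposed.
* Probabilities are not calibrated; the 0.5 threshold is a convention.
* WFDB record input is not supported; waveforms enter as CSV plus fiducial
  JSON.
* The model bundle persists via pickle and is not portable across library
  versions.
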