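# Methods

This note records the models, the parameter choices that matter, and what
the synthetic cohorts do and do not establish.

## Alignment: anchored virtual-lock-mass boxes

Mass measurement error on an Orbitrap-class instrument is multiplicative:
observed m/z = true m/z × (1 + e), with e on the parts-per-million scale,
so absolute error grows with mass. Each library metabolite therefore
anchors an interval ("VLM box") of half-width `ppm_tol` ppm around its
theoretical positive-mode mass, and a sample's peaks are assigned to the
box containing them. Choices:

* `ppm_tol` **default 5 ppm** — the instrument-level accuracy bound of the
  acquisition this pipeline targets. With a true mass-error sd of
  1.5 ppm, 5 ppm is ≈3.3σ, which is why ≥99% of synthetic peaks land on
  their generating metabolite.
* Raw intervals of neighbouring anchors can overlap; both are truncated at
  the **midpoint between the adjacent centers**, restoring disjointness.
  Containment is closed at the low bound, open at the high bound, so no
  m/z value belongs to two boxes.
* Boxes matched by zero peaks across all runs are dropped.
* Several peaks of one sample in one box are resolved by the
  `multi_peak_policy`: **max** (default; the most intense peak best
  represents the feature) or `sum`.
* Retention time is carried through but not used for matching by default;
  an optional RT gate (`rt_tol`) exists because the library may carry
  expected RTs. The approach is deliberately mass-based.

Filtering follows the standard untargeted workflow: features annotated in
the library as plant products or drugs/drug metabolites are removed, then
features observed in fewer than `min_presence_frac` (default **0.20**) of
samples are dropped. The boundary is inclusive — a feature present in
exactly 20% of samples survives, since the exclusion rule is "present in
*less than* 20%".

## Conditioning

Stage order is fixed as **align → exclude → presence-filter → log → QN →
KNN-impute**. Log first puts the multiplicative intensity scale on an
additive one; quantile normalization then operates on log intensities,
where distributional distortions are mildest; imputation runs last so the
imputer works in the final normalized space ("gap filling" of the matrix
the model will actually see).

**Train-referenced quantile normalization.** The reference is the
per-rank mean of the training samples' sorted observed values,
interpolated onto a common fractional-rank grid of length p (the feature
count), so samples with unequal observed counts contribute comparably.
Any sample — training or a single held-out serum — is projected by
replacing its observed values with the reference quantiles at their
fractional ranks (linear interpolation; ties share the mean of their tied
positions' targets; missing cells stay missing). On a complete matrix
this reduces exactly to textbook sort–mean–reassign QN, and projecting
columns one at a time is identical to projecting them stacked — there is
no way for test samples to influence each other or the reference.

**KNN gap filling.** Distance between two samples is the squared
Euclidean distance over co-observed features divided by the co-observed
count (otherwise samples with more missingness would look artificially
close). A missing cell is the unweighted mean of that feature among the
k nearest training samples that observe it — nearer neighbours lacking
the feature are skipped and the next nearest substituted; a feature no
training sample observes falls back to the training feature mean. A
training sample is never its own neighbour. `k` defaults to **5**, the
conventional small-k choice for metabolomics matrices; observed cells are
never altered.

**QC summary.** Process variability is summarized as the median, over
features present in 100% of pooled-QC replicate columns, of the
per-feature relative standard deviation (sd/mean on the natural intensity
scale).

## The two-stage screen

Stage 1 (the *gate*) is an L2-regularized logistic regression of cancer
(all four classes pooled) against normal controls, with per-class weights
inversely proportional to class frequency (the cohort is ≈4.5:1
cancer:control). The reported score is the **linear predictor**
x0 + Σ xi·Ii, not the sigmoid probability — thresholds live on that
scale, and any monotone transform leaves rankings and ROC unchanged.

* Regularization strength λ defaults to **1.0** (sklearn C = 1/λ);
  unregularized fitting at p ≫ n is ill-posed. Solver: lbfgs,
  tolerance 1e−8, iteration cap 10000 — deterministic given the data.
* The default decision threshold maximizes Youden's J on **out-of-fold
  training scores** (5-fold stratified CV over the training split). At
  p ≫ n the in-sample scores of the final fit are perfectly separated and
  optimistically spread, so a threshold placed on them sits inside an
  overfit margin and miscalls held-out controls; out-of-fold scores are
  still strictly training-only, so no test information is used. When a
  class has fewer than 5 training members the in-sample scores are used.
  Where the J-maximizing cut is a whole interval (separated scores), the
  center of the interval is taken — max-margin placement. A fixed
  threshold can always be supplied instead (`--threshold`).
* Calling rule: cancer iff score **strictly greater** than the threshold.

Stage 2 is one-vs-rest over the four cancer classes, fitted on the cancer
training samples only; each component is exactly a binary fit under the
one-vs-rest relabeling and shares the feature order. Class weighting is
applied here too (each one-vs-rest problem is ≈1:3 imbalanced). The
layered prediction gates first: gate-negative samples are final "normal"
and never receive a cancer class; gate-positive samples get the class of
the maximum one-vs-rest score, ties broken by the fixed class order
(endometrial, breast, cervical, ovarian).

One-vs-rest **evaluation** folds the normal controls into each class's
control group by default (`include_normals=True`): a deployed screen sees
healthy sera among the "rest". A sample counts predicted-positive either
by final-label equality (layered output) or by its class score exceeding
a threshold — both paths are exposed.

## PLS-DA

Cohort separation is quantified by partial least squares against one-hot
class indicators on the mean-centered, unit-scaled matrix. R²(k) is the
cumulative fraction of indicator variance explained in-sample with k
latent components; Q²(k) is the cross-validated counterpart
1 − PRESS/TSS, computed over **seeded stratified 7-fold** CV (the fold
count is a conventional choice). The first latent weight vector equals
the dominant singular direction of Xᵀ Y up to sign, which the test suite
checks against an independent SVD. Permuting labels drives Q² to ≈0 or
below; that negative control is also part of the suite.

## Ranking and panel selection

Features are ranked by |coefficient| of a fitted model, ties broken
lexicographically by feature id. Forward selection refits the gate on the
top-1, top-2, … prefix and stops at the first prefix meeting the
sensitivity/specificity targets **on a caller-supplied evaluation split**
— selection metrics are never computed on the data used for the refits,
so the reported panel size carries no leakage optimism. A no-refit
variant (restrict the full model's coefficients to the prefix,
re-threshold on training scores) is available where refitting is too
expensive.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed to the study conditions it stands in for:

| parameter | default | meaning |
|---|---|---|
| `n_per_class` | 250/304/303/250/262 | normal / endometrial / breast / cervical / ovarian samples |
| `library_size` | 2000 | endogenous reference metabolites |
| `n_contaminants` | 100 | plant/drug library entries |
| `n_signature_per_class` | 40 | discriminative metabolites per cancer class (disjoint across classes) |
| `effect_log2fc` | 1.5 | signature shift magnitude, sign drawn per metabolite |
| `sigma_ppm` | 1.5 | sd of relative mass error (instrument bound: <5 ppm) |
| `base_log_intensity_mean/sd` | 13.0 / 0.5 | ln-scale intensity distribution (≈4.4e5 counts, ≈65% CV) |
| `missing_rate_random` | 0.05 | missing-completely-at-random rate |
| `missing_intensity_knee` / width | 11.0 / 0.7 | logistic intensity-dependent missingness on the ln scale |
| `batch_scale_sd` | 0.1 | per-sample multiplicative scale jitter (ln-scale sd) |
| scan range | 66.7–1000 Da | library masses, log-uniform with guaranteed 4σ relative spacing |

The within-feature ln-sd of 0.5 realizes the intended planted-separability
regime: with ≥20 signature metabolites per class at |log2FC| ≥ 1, a linear
classifier on the noiseless latent intensities has a Bayes error near
zero (the pooled signature direction separates classes by ≈6σ), so
pipeline recovery failures indict the pipeline, not the data. It is also
a realistic serum LC-MS variability; at ln-sd 1.0 (≈130% CV) the same
design would be only ≈3σ separable and no pipeline could meet the
recovery contract.

RT per metabolite is a fixed library draw in [0.5, 11] min plus 0.05 min
per-sample jitter. Pooled-QC replicates average every sample's
contribution per metabolite on the natural scale (absent peaks contribute
zero, as in a physical pool) and add fresh multiplicative technical
noise; the generator's ground truth supplies the peak→metabolite identity
this pooling needs, which is why the QC operation takes the GroundTruth
object explicitly.

**What the generator does not emulate:** adduct/isotope multiplicity (one
feature per metabolite — the real collapse from >20k spectral features to
thousands of identified metabolites is not modelled), chromatographic
peak shapes, RT drift/warping across runs, correlated metabolite modules,
and non-log-normal intensity tails. Passing recovery tests therefore
demonstrates correctness of the pipeline's mechanics under its stated
model, not field performance on real sera.

## Numerical and degenerate-input conventions

* All floats written to disk use shortest round-trip representation;
  model and imputer serialization round-trips bit-exactly.
* Readers never silently drop rows; validation errors carry the offending
  row or cell coordinates.
* Absent peaks are absent records — never zero intensities; an undefined
  metric ratio (empty positive or control group) is reported as absent,
  never 0.
* Every stochastic step (library, cohort, split, CV folds, QC noise) is
  driven by an explicit seed; a full pipeline run is byte-reproducible.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the cohort at 100 samples
per class against a 500 + 50 metabolite library (40 signatures per class)
— large enough that the gate and one-vs-rest models operate in the
p ≫ n regime the full-scale study occupies, while a complete end-to-end
run takes seconds. The generator's own defaults (above) reproduce the
full cohort geometry when heavier runs are wanted.

## Known limitations

* The anchored-VLM variant requires a library; de-novo (library-free)
  box detection is out of scope.
* Quantile normalization assumes train and test samples share a common
  intensity-distribution shape; a strong global distribution shift (e.g.
  a different extraction protocol) violates the stored-reference premise.
* The per-class decision thresholds of the one-vs-rest evaluation default
  to the layered final-label rule; score-threshold evaluation is exposed
  but choosing those thresholds is left to the caller.
* Real coefficient sets from the original full-scale study are not
  reproducible without its (undeposited) raw data; the model JSON format
  is designed so externally published coefficient vectors could be
  imported and applied.
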