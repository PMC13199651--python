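# Methods

This note records the models the package implements, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical conventions a maintainer needs.

## Synthetic cohorts

The generator emulates merged public colorectal-cancer cohorts on the log2
scale:

    x_gs = b_g + e·1[s ∈ class 1, g informative] + γ_{g,c(s)} + λ_{g,c(s)}·ε_gs

* gene baselines `b_g ~ N(8, 2)` — the magnitude range of log2 microarray
  intensities / log2(FPKM+1);
* a class effect `e` (log2 units) added to a designated informative-gene
  subset of class-1 samples **before** batch effects, so biology is
  confounded with batch (the realistic hard case);
* per-cohort additive offsets `γ ~ N(0, batch_shift_sd)` and multiplicative
  residual scales `λ = exp(N(0, batch_scale_sd))`, exactly the
  location/scale family the empirical-Bayes correction assumes — so the
  correction model is correctly specified and recovery is a meaningful test;
* residuals `ε ~ N(0, noise_sd)`.

Per-cohort positive counts are deterministic (`round(prevalence·n)`);
which samples are positive is randomized. All randomness flows from one
`numpy.random.Generator` seeded from the config; identical config + seed is
bit-identical.

What the generator does **not** emulate: count-level RNA-seq noise
(negative-binomial reads), zero inflation/dropout, gene–gene correlation
structure, probe-level artifacts, or nonlinear platform distortions.
Passing recovery tests on this generator therefore demonstrates that the
pipeline's statistics do what they claim under their own model assumptions;
it does not certify performance on real cross-platform data, where the
additive/multiplicative batch model is only an approximation.

Reference study conditions used by the test-suite and the acceptance
script, chosen to mirror the scale of the screening problem the package
targets: a 900-sample draw at 620 genes with 50 informative genes at effect
1.5 (600 development + 300 external samples); a 3-cohort confounded study
(60 samples per cohort, prevalences 0.3/0.5/0.7, `batch_shift_sd` 2,
class effect 2.0, `noise_sd` 0.5) for batch-correction recovery; 1000-gene
null and signal panels for differential-expression calibration; and a
150-sample, 60-gene problem for the bit-determinism check.

## Batch correction

Parametric empirical-Bayes location/scale adjustment. Per gene: OLS fit of
batch cell means plus the protected binary covariate; standardization by
the grand (batch-size-weighted) mean and pooled MLE residual variance;
per-batch location `γ̂_gb` and scale `δ̂²_gb` estimates shrunk by the
standard iterative posterior updates under a Normal prior for γ (mean and
variance = moments of γ̂ across genes) and an inverse-gamma prior for δ²
(shape/scale by moments of δ̂² across genes); back-transformation restores
the grand mean and covariate effects. The implementation agrees with the
reference R implementation (`sva::ComBat` with a model matrix) to ~1e-14;
a cross-check test freezes that equivalence at 1e-8.

Conventions:

* Batches named in `holdout_batches` are excluded from every estimation
  step and returned bit-identical — the protocol for keeping an external
  test cohort independent of integration.
* Genes constant within any fitting batch (detected by exact range, not
  floating-point variance) are dropped and reported: the scale model is
  undefined for them.
* A single fitting batch is returned unchanged (nothing to correct).
* Correction is only asymptotically idempotent: EB shrinkage leaves O(1/n)
  residual batch moments, so a second pass moves values by a few percent of
  a gene's spread at 40 samples/batch and <1% at 200/batch. The test pins
  the 200/batch regime.

Silhouette scores are computed in full gene space with Euclidean distance
(no PCA reduction — a documented convention, since a reduced space would
make the score depend on component count). Singleton clusters and the
a=b=0 degenerate case score 0.

## Differential expression and the functional pool

Moderated t: pooled two-group variance `s²_g` with `d_g = n−2`; the prior
`(d₀, s₀²)` is fitted by method of moments on `log s²_g` (mean and variance
of `log s² − ψ(d_g/2) + log(d_g/2)`, with `d₀` from inverting the trigamma
function); posterior variance `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`;
two-sided p from t with `d₀+d_g` df (Normal when `d₀ = ∞`). This matches
the reference R implementation (`limma::eBayes`) to ≲0.2% relative on t —
the residual difference is the hyperprior estimator (closed-form moments
here vs. profiled F-distribution fitting there). Welch's t is available as
a model-free cross-check mode.

Selection is `|log2FC| ≥ 1` (inclusive, with log2FC = mean₁ − mean₀) and
raw `P < 0.05` — deliberately **no** multiple-testing correction, because
the pooling rule is a raw-P gate intersected with a curated metabolic
panel; a Benjamini–Hochberg column is emitted for users who want it.
Degenerate genes (identical values in both classes) follow t = 0, p = 1.
The metabolic panel is supplied by the user as a plain-text gene list; gene
matching is exact-string, so identifiers must be pre-mapped.

## The screener

Architecture and training recipe as in the README. Implementation choices
that were genuinely open:

* **Convolution padding**: none ("valid"), stride 1; pooling stride = pool
  size with floor on odd lengths. The length chain L → L−4 → ⌊/2⌋ → −4 →
  ⌊/2⌋ is asserted explicitly (620 → 616 → 308 → 304 → 152; flatten
  64·152). Inputs shorter than 26 are rejected for the default geometry —
  a conservative documented floor well above where the chain arithmetically
  collapses (16).
* **Gene order along the convolution axis** is the sorted panel order.
  Expression panels have no natural spatial ordering, so the order is a
  fixed arbitrary convention; fixing it canonically makes models
  reproducible and transferable.
* **Initialization**: Glorot-uniform, seeded; biases zero. **Optimizer**:
  Adam (β₁ 0.9, β₂ 0.999, ε 1e-7). Probabilities are clipped to
  [1e-7, 1−1e-7] inside the cross-entropy; the clip zeroes the gradient of
  saturated outputs.
* **Early stopping** restores the best-validation-loss weights (making
  val_loss the actual selection criterion it monitors); the LR-plateau
  counter resets on improvement and after each halving.
* **Scaling**: per-fold z-score with population sd; zero-sd features are
  flagged and mapped to 0. Scaler statistics come from the k−1 training
  folds only and are serialized with the fold, because inference must
  standardize new samples with the fold-specific training statistics.
* Everything is float32 driven by explicit RNG streams (init, shuffling,
  dropout), so two runs with one seed agree bit-for-bit on the same BLAS;
  the determinism test asserts TRS agreement to 1e-6, far above any
  plausible BLAS-reordering jitter.
* No class weighting or oversampling; imbalance is handled at evaluation
  (balanced accuracy, PR AUC, imbalance flags below a 10% minority
  fraction).

## Risk score, thresholds, attribution

TRS is the exact arithmetic mean of the five fold probabilities (no
tolerance). Classification is the inclusive rule (class 1 iff
TRS ≥ threshold). The Youden threshold maximizes J = sensitivity +
specificity − 1 over the unique observed scores plus a sentinel above the
maximum (the predict-nothing rule); the maximizer is always attained at an
observed score under the ≥ rule, and ties break toward the smallest
threshold. An exhaustive-search oracle test enforces exact agreement.

Attribution uses Spearman ρ (average ranks on ties) between each gene and
TRS, ranked by |ρ| with ties broken by gene id; p-values use the
t-approximation with n−2 df and are descriptive (no multiplicity
correction; an FDR column is provided). Core features are the sorted
intersection of two cohorts' top-k lists (default k = 50). A meaningful
"second cohort" must share the population of the first (same gene
baselines); scoring a cohort simulated with unrelated baselines pushes the
network into saturation and the attribution into noise.

## Evaluation

ROC AUC is computed from midranks (exactly the Mann–Whitney pair-counting
probability, ties counted half). PR AUC is the average-precision step sum
— not trapezoidal interpolation, which overestimates PR area. Both are
enforced against O(n²) brute-force oracles on 500 random tied instances.
Zero-denominator rates report 0 with a flag naming the metric.

**Permutation nulls.** Chance-level checks permute the *entire* label
vector before any split and evaluate against the permuted labels. Training
on permuted labels but evaluating against the true labels is not a chance
baseline on separable mixture data: variance-sensitive models (Gaussian
naive Bayes most visibly) assign the mixture's outliers to whichever
permuted class drew a slightly larger fitted variance and thereby recover
the true structure — we measured hold-out AUC 0.997 for a
permuted-label-trained GNB under that flawed protocol.

The classical benchmark fits the ten named families at library defaults
with fixed seeds on train-scaled features; optional back-ends (LightGBM,
XGBoost) are reported as `skipped: <reason>` when unavailable, never
silently dropped. LODO re-runs merging, batch correction (held-out cohort
excluded), feature pooling, ensemble training, and training-side Youden
thresholding for every held-out cohort, and records the training cohort
names, sample ids, and a sha256 of the exact training matrix so exclusion
is auditable; a `fixed_panel` fast mode skips pool re-estimation for
testing. Cohorts with a single class get `roc_auc: null` with a reason
(Brier and counting metrics still reported); minority fractions below 10%
raise an imbalance flag.

## Known limitations

* The batch model is additive/multiplicative per gene; nonlinear platform
  effects (probe saturation, GC bias) are out of scope.
* Gene identifiers are matched as exact strings; no alias/probe resolution.
* The moderated-t hyperprior uses closed-form moments, not profiled
  maximum likelihood; t-statistics can differ from the R reference in the
  third decimal.
* The network is CPU-oriented numpy; it is fast for panel-sized inputs
  (hundreds of features) but not intended for transcriptome-wide inputs.
* Calibration of the output probabilities (Platt/isotonic) is not
  implemented; the Youden cutoff is the supported remedy for cohort shift.
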