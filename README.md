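# trscreen

Metastasis-risk screening from multicohort bulk transcriptomes.

Distinguishing metastatic from primary colorectal tumors from bulk expression
requires pooling many public cohorts measured on different platforms. That
raises three coupled problems: platform batch effects confound the biological
signal; the informative features are a small metabolic subset of the
transcriptome; and any cross-validated classifier leaks information unless
standardization, feature pooling, and thresholding are all confined to
training data. `trscreen` implements the full pipeline for this setting and
ships a synthetic-cohort generator with known ground truth, so every stage is
testable without downloading any cohort.

## The model

**Harmonization.** Cohorts are merged on their common genes (sorted order),
RNA-seq values are log2(x+1)-transformed, and duplicate samples across
cohorts are removed.

**Batch correction.** Platform effects are removed with parametric
empirical-Bayes location/scale adjustment (ComBat): per gene *g* and batch
*b*, the model is

    x_gbs = α_g + X β_g + γ_gb + δ_gb ε_gbs

with disease status as a protected covariate in the design *X*. Batch
locations γ and scales δ² are shrunk toward Normal / inverse-gamma priors
(moments estimated across genes) and removed; the covariate effect is
restored. Correction quality is measured by the mean silhouette width
s(i) = (b−a)/max(a,b) over batch labels — lower is better mixing. A
designated hold-out cohort can be excluded from all fitting and passes
through untouched.

**Functional gene pool.** Genes differential between metastatic (1) and
primary (0) samples at |log2FC| ≥ 1 and P < 0.05 (empirical-Bayes moderated
t, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), or Welch t as a cross-check),
intersected with a user-supplied metabolic gene panel, become the
classifier's input panel in sorted gene order.

**Screener.** A 1-D convolutional network along the panel axis:
Conv(32 filters, kernel 5, ReLU) → MaxPool(2) → Dropout 0.3 →
Conv(64, kernel 5, ReLU) → MaxPool(2) → Dropout 0.4 → Flatten →
Dense(64, ReLU) → Dropout 0.5 → Dense(1, sigmoid), trained with Adam
(lr 0.001) on binary cross-entropy, batch size 32, ≤ 50 epochs, early
stopping (patience 10 on validation loss, best weights restored) and LR
halving on a 5-epoch plateau. Training uses an 80:20 stratified split and
5-fold stratified cross-validation; each fold's z-score scaler is fitted on
its own training folds only. The five fold models are the ensemble.

**Transcriptomic risk score (TRS).** For a sample x,

    TRS(x) = (1/5) Σᵢ Pᵢ(metastasis | x)

the arithmetic mean of the five fold probabilities. Classification is
TRS ≥ threshold, at the 0.5 default or a Youden-index cutoff
(maximizing sensitivity + specificity − 1 over observed scores). Feature
attribution ranks genes by |Spearman ρ| against TRS; the intersection of two
cohorts' top-50 lists gives the core feature set.

**Evaluation.** ROC AUC (Mann–Whitney form), PR AUC (average-precision step
sum), Brier score, balanced accuracy, a 10-family classical-classifier
benchmark (logistic regression, RBF SVM, k-NN, Gaussian NB, random forest,
decision tree, gradient boosting, AdaBoost, LightGBM, XGBoost), and a
leave-one-dataset-out (LODO) protocol that withholds a whole cohort from
merging, correction, pooling, and training before scoring it.

## Worked example

Simulate three confounded cohorts (prevalences 0.3/0.5/0.7, additive batch
shifts of sd 2), correct them, pool features, train, and score:

```bash
trscreen simulate --config sim.yaml --out data/
# wrote 400 genes x 180 samples to data
trscreen correct-batch --expr data/expression.tsv --meta data/metadata.tsv \
    --out corrected.tsv --report batch.json
# corrected 180 samples; dropped 0 genes
trscreen pool-features --expr corrected.tsv --meta data/metadata.tsv \
    --metabolic metabolic.txt --out pool.txt
# functional gene pool: 40 genes
trscreen train --expr corrected.tsv --meta data/metadata.tsv \
    --panel pool.txt --seed 42 --out model/
# trained 5 folds (final val accuracy: 1.000, 1.000, 1.000, 1.000, 1.000)
trscreen score --model model/ --expr corrected.tsv --out trs.tsv
# scored 180 samples at threshold 0.5000
```

`batch.json` records the mixing improvement the correction achieved:

```json
{
 "silhouette_before": 0.7120050523124525,
 "silhouette_after": -0.022240208159903983,
 "n_batches": 3
}
```

Before correction, samples cluster by cohort (silhouette 0.71 over batch
labels); afterwards the cohorts are fully intermixed (−0.02). The recovered
40-gene pool matched the simulation's 40 informative genes exactly, and
`trs.tsv` holds one row per sample with the five fold probabilities, the
TRS, and the predicted class — all 180 training-cohort samples were
classified correctly at the 0.5 cutoff. Every command also writes a
`run_manifest.json` with input hashes, the effective configuration, and the
seed.

The same stages are available as library functions
(`trscreen.generate_multicohort`, `combat_adjust`, `build_feature_pool`,
`fit_ensemble`, `compute_trs`, `lodo_evaluate`, …).

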