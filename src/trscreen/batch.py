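"""Empirical-Bayes location/scale batch correction with covariate protection.

Implements the parametric ComBat adjustment: per gene, fit a linear model
with batch indicators and the protected biological covariate; standardize
residual variation; estimate per-batch location (gamma) and scale (delta^2)
parameters; shrink them toward pooled priors (Normal for gamma,
inverse-gamma for delta^2, hyperparameters by method of moments across
genes); remove the shrunken batch effects and restore the grand mean and
covariate effects.

Samples from batches named in ``holdout_batches`` are excluded from all
fitting and returned untouched — the protocol used when an external test
cohort must stay independent of every integration step.

Correction efficacy is quantified by the mean silhouette width over batch
labels (Euclidean distance in full gene space): lower = better mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ContractError, DomainError
from .io import ExpressionMatrix


@dataclass
class BatchCorrectionReport:
    silhouette_before: float
    silhouette_after: float
    n_batches: int
    genes_dropped: list[str] = field(default_factory=list)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch's gamma*, delta*^2 (per gene)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def combat_adjust(
    matrix: ExpressionMatrix,
    batch: Sequence[str],
    covariate: Sequence[int] | None = None,
    holdout_batches: Sequence[str] = (),
) -> tuple[ExpressionMatrix, list[str]]:
    """Parametric empirical-Bayes batch adjustment.

    Parameters
    ----------
    matrix
        genes x samples expression on the log2 scale.
    batch
        per-sample batch label, aligned with ``matrix.sample_ids``.
    covariate
        per-sample binary disease status to protect; its effect is removed
        before standardization and restored afterwards.  ``None`` fits an
        intercept-and-batch model only.
    holdout_batches
        batch labels excluded from fitting; their samples pass through
        bit-identically.

    Returns
    -------
    (adjusted matrix, dropped gene ids)
        Genes with zero variance within any fitting batch (or zero pooled
        variance) are dropped from the output and reported.
    """
    batch = np.asarray(batch, dtype=object)
    if batch.shape[0] != len(matrix.sample_ids):
        raise ContractError("batch labels do not align with matrix samples")
    fit_mask = ~np.isin(batch, np.asarray(list(holdout_batches), dtype=object))
    fit_batches = sorted(set(batch[fit_mask]))
    if len(fit_batches) < 1:
        raise ContractError("no batches left to fit after hold-out exclusion")
    counts = {b: int(np.sum(batch[fit_mask] == b)) for b in fit_batches}
    singletons = [b for b, n in counts.items() if n < 2]
    if singletons:
        raise ContractError(f"each fitting batch needs >= 2 samples; too small: {singletons}")

    Y = matrix.values[:, fit_mask]
    n_fit = Y.shape[1]
    batch_fit = batch[fit_mask]

    if len(fit_batches) == 1:
        # nothing to correct; keep contract of dropping nothing
        return matrix.copy(), []

    # drop genes unusable for the location/scale model (constant within a
    # batch; ptp is exact where float variance of a constant may not be)
    within_zero = np.zeros(matrix.values.shape[0], dtype=bool)
    for b in fit_batches:
        sub = Y[:, batch_fit == b]
        within_zero |= np.ptp(sub, axis=1) == 0.0
    keep = ~within_zero
    dropped = [g for g, bad in zip(matrix.gene_ids, within_zero) if bad]
    Y = Y[keep]
    n_genes = Y.shape[0]
    if n_genes == 0:
        raise ContractError("all genes have zero variance within some batch")

    # design: batch indicators (cell-means coding) + covariate columns
    batch_design = np.stack([(batch_fit == b).astype(float) for b in fit_batches], axis=1)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape[0] != len(matrix.sample_ids):
            raise ContractError("covariate does not align with matrix samples")
        if np.any(~np.isfinite(cov[fit_mask])):
            raise ContractError("covariate must be defined for all fitting samples")
        X = np.concatenate([batch_design, cov[fit_mask, None]], axis=1)
    else:
        X = batch_design
    n_batch = len(fit_batches)

    # per-gene OLS: B_hat rows are coefficients, genes in columns
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)  # (p, genes)
    batch_sizes = np.array([counts[b] for b in fit_batches], dtype=float)
    grand_mean = (batch_sizes / n_fit) @ B_hat[:n_batch]  # (genes,)
    fitted = (X @ B_hat).T
    var_pooled = ((Y - fitted) ** 2).mean(axis=1)  # MLE residual variance
    zero_var = var_pooled == 0.0
    if zero_var.any():
        extra = [g for g, keepit in zip(matrix.gene_ids, keep) if keepit]
        dropped += [g for g, z in zip(extra, zero_var) if z]
        keep2 = ~zero_var
        Y, B_hat, grand_mean, var_pooled = Y[keep2], B_hat[:, keep2], grand_mean[keep2], var_pooled[keep2]
        n_genes = Y.shape[0]

    # standardize: remove grand mean + covariate effects, unit pooled variance
    stand_mean = grand_mean[:, None] * np.ones((1, n_fit))
    if covariate is not None:
        stand_mean = stand_mean + np.outer(B_hat[n_batch], cov[fit_mask])
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    # per-batch EB shrinkage of location and scale
    Z_adj = np.empty_like(Z)
    for j, b in enumerate(fit_batches):
        cols = batch_fit == b
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        a, b_pr = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star, delta_star = _it_sol(Zb, gamma_hat, delta_hat, gamma_bar, t2, a, b_pr)
        Z_adj[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    corrected_fit = Z_adj * sd + stand_mean

    # reassemble: hold-out samples untouched, dropped genes removed
    keep_genes = [g for g in matrix.gene_ids if g not in set(dropped)]
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    out = matrix.values[[gene_pos[g] for g in keep_genes]].copy()
    out[:, fit_mask] = corrected_fit
    return ExpressionMatrix(keep_genes, list(matrix.sample_ids), out), dropped


def mean_silhouette(matrix: ExpressionMatrix, labels: Sequence[str]) -> float:
    """Mean silhouette width of samples under ``labels`` (Euclidean, full gene space).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    same-label samples and b(i) the smallest mean distance to another label.
    Singleton-label samples score 0; so does the a = b = 0 degenerate case.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != len(matrix.sample_ids):
        raise ContractError("labels do not align with matrix samples")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ContractError("mean_silhouette needs >= 2 label levels")
    X = matrix.values.T  # samples x genes
    D = cdist(X, X)
    n = X.shape[0]
    scores = np.zeros(n)
    masks = {lv: labels == lv for lv in levels}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention: s = 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[lv]].mean() for lv in levels if lv != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


def correction_report(
    before: ExpressionMatrix,
    after: ExpressionMatrix,
    batch: Sequence[str],
) -> BatchCorrectionReport:
    """Silhouette over batch labels before and after correction.

    ``after`` may have fewer genes than ``before`` (dropped zero-variance
    genes); sample ids must match exactly.
    """
    if before.sample_ids != after.sample_ids:
        raise ContractError("before/after matrices have different samples")
    if not set(after.gene_ids) <= set(before.gene_ids):
        raise ContractError("after matrix contains genes absent from before matrix")
    return BatchCorrectionReport(
        silhouette_before=mean_silhouette(before, batch),
        silhouette_after=mean_silhouette(after, batch),
        n_batches=len(set(batch)),
    )
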