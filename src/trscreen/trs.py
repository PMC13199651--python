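"""Transcriptomic risk score (TRS), thresholding, and feature attribution.

TRS is the arithmetic mean of the k fold-model metastasis probabilities for
a sample; higher values mean greater predicted risk.  Classification uses
the inclusive rule (risk class 1 when TRS >= threshold) at the default
cutoff 0.5, or at a data-driven cutoff maximizing the Youden index
J = sensitivity + specificity - 1 over observed score values.

Attribution correlates each gene's expression with TRS across samples
(Spearman rho, average ranks on ties; two-sided p by the t approximation)
and ranks genes by |rho|.  The "core" feature set of two cohorts is the
intersection of their top-k lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DomainError
from .io import ExpressionMatrix


def compute_trs(fold_probs: np.ndarray) -> np.ndarray:
    """Column-wise mean of the (k x n_samples) fold-probability matrix."""
    fold_probs = np.asarray(fold_probs, dtype=np.float64)
    if fold_probs.ndim != 2:
        raise ContractError("fold_probs must be a k x n_samples matrix")
    if np.any(fold_probs < 0.0) or np.any(fold_probs > 1.0):
        raise DomainError("fold probabilities must lie in [0, 1]")
    return fold_probs.mean(axis=0)


def classify(trs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where TRS >= threshold (inclusive), else 0."""
    trs = np.asarray(trs, dtype=np.float64)
    return (trs >= threshold).astype(np.int64)


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1 under the >= rule.

    Candidates are the unique observed scores plus a sentinel above the
    maximum (the predict-nothing rule); ties in J break toward the smallest
    threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must align")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ContractError("youden_threshold needs both classes present")
    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)  # all-negative rule
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n1
        spec = np.sum(~pred & (labels == 0)) / n0
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (smallest) maximizer wins
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class AttributionResult:
    table: pd.DataFrame  # gene_id, rho, p_value, rank (1 = largest |rho|)

    def top(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ContractError(f"top_k={k} exceeds {len(self.table)} attributed genes")
        return list(self.table.sort_values("rank").head(k)["gene_id"])


def attribute_features(matrix: ExpressionMatrix, trs) -> AttributionResult:
    """Spearman correlation of every gene with TRS; rank by |rho| descending.

    Rank ties break lexicographically by gene id.  P-values use the
    t-distribution approximation with n - 2 degrees of freedom and are
    descriptive (no multiplicity correction); an ``fdr`` column is provided
    for users who want one.
    """
    trs = np.asarray(trs, dtype=np.float64)
    n = trs.shape[0]
    if n < 3:
        raise ContractError("attribute_features needs >= 3 samples")
    if len(matrix.sample_ids) != n:
        raise ContractError("TRS vector does not align with matrix samples")
    if np.all(trs == trs[0]):
        raise ContractError("TRS is constant; correlation undefined")

    trs_rank = stats.rankdata(trs)
    gene_ranks = np.apply_along_axis(stats.rankdata, 1, matrix.values)
    tr = trs_rank - trs_rank.mean()
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr**2).sum(axis=1) * (tr**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, gr @ tr / np.where(denom > 0, denom, 1.0), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t_stat), n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({"gene_id": matrix.gene_ids, "rho": rho, "p_value": p})
    table["fdr"] = _bh(p)
    order = np.lexsort((table["gene_id"].to_numpy(), -np.abs(rho)))
    ranks = np.empty(len(table), dtype=np.int64)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return AttributionResult(table.sort_values("rank").reset_index(drop=True))


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def core_features(
    attr_a: AttributionResult, attr_b: AttributionResult, top_k: int = 50
) -> list[str]:
    """Sorted intersection of the two cohorts' top-k |rho| gene lists."""
    universe_a = set(attr_a.table["gene_id"])
    universe_b = set(attr_b.table["gene_id"])
    if universe_a != universe_b:
        raise ContractError("attributions cover different gene universes")
    return sorted(set(attr_a.top(top_k)) & set(attr_b.top(top_k)))


def trs_table(
    sample_ids: list[str],
    fold_probs: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sample report: fold probabilities, TRS, threshold, predicted class."""
    fold_probs = np.asarray(fold_probs, dtype=np.float64)
    trs = compute_trs(fold_probs)
    pred = classify(trs, threshold)
    data = {"sample_id": sample_ids}
    for i in range(fold_probs.shape[0]):
        data[f"P{i + 1}"] = fold_probs[i]
    data["TRS"] = trs
    data["threshold"] = threshold
    data["predicted_class"] = pred
    return pd.DataFrame(data)
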