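"""Two-group differential expression and functional gene pooling.

The screening panel is built in two steps: (1) differential expression
between metastatic (1) and primary (0) samples on the log2 scale, with the
selection rule |log2FC| >= 1 and raw P < 0.05 (no multiplicity correction by
default — the pooling rule is a raw-P gate; an FDR column is available for
users); (2) intersection of the selected genes with a curated metabolic
gene panel, yielding the functional gene pool that becomes the classifier
input.

Two test statistics are offered:

``moderated_t``
    Empirical-Bayes moderated t: per-gene pooled variance s2_g with
    d_g = n - 2 degrees of freedom is shrunk toward a common prior,
    s2_post = (d0*s0^2 + d_g*s2_g) / (d0 + d_g), where the prior degrees of
    freedom d0 and location s0^2 are estimated by method of moments on
    log s2_g (matching the scaled-F model: log s2_g has a shifted
    log-F(d_g, d0) distribution). P-values use d0 + d_g degrees of freedom.

``welch_t``
    The ordinary Welch unequal-variance t-test (a model-free cross-check).

Degenerate genes (zero variance everywhere, zero fold change) follow the
convention t = 0, p = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ContractError, MergeError
from .io import ExpressionMatrix, GenePanel

DEFAULT_LFC_MIN = 1.0
DEFAULT_P_MAX = 0.05


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log sample variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2[ok].mean()) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid = e_var - special.polygamma(1, d_g / 2.0)
    if resid <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def differential_expression(
    matrix: ExpressionMatrix,
    labels,
    method: str = "moderated_t",
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Per-gene two-group test; returns a table with a ``passes`` column.

    log2fc is mean(class 1) - mean(class 0) on the (log2-scale) input.
    ``passes`` is |log2fc| >= lfc_min AND p < p_max.  An ``fdr`` column
    (Benjamini-Hochberg) is included for optional downstream use.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != len(matrix.sample_ids):
        raise ContractError("labels do not align with matrix samples")
    if method not in ("moderated_t", "welch_t"):
        raise ContractError(f"unknown method {method!r}")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ContractError(f"each class needs >= 2 samples (got {n0} / {n1})")

    X1 = matrix.values[:, labels == 1]
    X0 = matrix.values[:, labels == 0]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    log2fc = m1 - m0
    v1 = X1.var(axis=1, ddof=1)
    v0 = X0.var(axis=1, ddof=1)

    if method == "moderated_t":
        d_g = float(n1 + n0 - 2)
        s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / d_g  # pooled
        d0, s0_2 = _fit_variance_prior(s2, d_g)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df = np.inf
        else:
            s2_post = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
            df = d0 + d_g
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        if np.isinf(df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(X1, X0, axis=1, equal_var=False)
        t = np.nan_to_num(res.statistic, nan=0.0, posinf=np.inf, neginf=-np.inf)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance genes: t undefined; convention p=1 when fc=0, else p=0
        degenerate = (v1 == 0) & (v0 == 0)
        p = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), p)
        p = np.nan_to_num(p, nan=1.0)

    p = np.clip(p, np.finfo(float).tiny, 1.0)  # t = 0 already yields p = 1
    fdr = _benjamini_hochberg(p)
    passes = (np.abs(log2fc) >= lfc_min) & (p < p_max)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "passes": passes,
        }
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def select_degs(
    results: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> set[str]:
    """Genes passing |log2fc| >= lfc_min and p < p_max under supplied thresholds."""
    if results.empty:
        raise ContractError("empty differential-expression table")
    mask = (results["log2fc"].abs() >= lfc_min) & (results["p_value"] < p_max)
    return set(results.loc[mask, "gene_id"])


def intersect_panel(degs: set[str], metabolic: GenePanel, name: str = "functional_pool") -> GenePanel:
    """Intersect selected genes with the metabolic panel -> functional gene pool."""
    if not degs:
        raise ContractError("empty DEG set")
    pool = sorted(degs & set(metabolic.gene_ids))
    if not pool:
        raise MergeError("DEGs and metabolic panel are disjoint; screener needs >= 1 feature")
    return GenePanel(pool, name=name)


def build_feature_pool(
    matrix: ExpressionMatrix,
    labels,
    metabolic: GenePanel,
    method: str = "moderated_t",
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> tuple[GenePanel, pd.DataFrame]:
    """DE + threshold + metabolic intersection in one call."""
    table = differential_expression(matrix, labels, method=method, lfc_min=lfc_min, p_max=p_max)
    degs = select_degs(table, lfc_min=lfc_min, p_max=p_max)
    return intersect_panel(degs, metabolic), table
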