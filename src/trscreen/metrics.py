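"""Classification metrics, the classical-classifier benchmark, and the
leave-one-dataset-out (LODO) generalization protocol.

Metric definitions are deliberately elementary so they can be verified
against brute-force oracles:

* ROC AUC is the Mann-Whitney probability
  (#concordant positive-negative pairs + 0.5 * #ties) / (n1 * n0),
  computed via midranks (exact with ties).
* PR AUC uses the average-precision step form
  sum_i (R_i - R_{i-1}) * P_i over descending unique score cut points
  (trapezoidal interpolation would overestimate PR area).
* The Brier score is the mean squared error of the probability forecast.

The benchmark harness fits the ten classical families named in the study
(logistic regression, RBF SVM, k-NN, Gaussian naive Bayes, random forest,
decision tree, gradient boosting, AdaBoost, LightGBM, XGBoost) at library
defaults with fixed seeds, on identically scaled features; unavailable
optional back-ends are reported as skipped, never silently dropped.

LODO withholds one whole cohort from merging, batch correction, feature
pooling, and training, then scores it — the protocol for estimating
cross-cohort generalization.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .batch import combat_adjust
from .diffexpr import build_feature_pool
from .errors import ContractError, DomainError
from .io import ExpressionMatrix, GenePanel, merge_cohorts, subset_panel
from .nn import NetworkSpec, TrainConfig
from .screener import Scaler, fit_ensemble, fit_scaler, predict_ensemble
from .trs import classify, compute_trs, youden_threshold

logger = logging.getLogger(__name__)

IMBALANCE_FLAG_PREVALENCE = 0.10


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predictions) -> ConfusionMatrix:
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ContractError("labels and predictions differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def basic_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy/precision/recall/specificity/balanced accuracy from counts.

    Zero-denominator rates are reported as 0.0 with a flag listing which.
    """
    if cm.n == 0:
        raise ContractError("empty confusion matrix")
    flags = []

    def _rate(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = _rate(cm.tp, cm.tp + cm.fp, "precision")
    recall = _rate(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _rate(cm.tn, cm.tn + cm.fp, "specificity")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.n,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "balanced_accuracy": (recall + specificity) / 2.0,
        "zero_denominator": flags,
    }


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC via midranks; exact under ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ContractError("roc_auc needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks -> 0.5 credit for ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def pr_auc(scores, labels) -> float:
    """Average precision: sum of (recall step) * precision at each cut point."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n1 = int((labels == 1).sum())
    if n1 == 0:
        raise ContractError("pr_auc needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # evaluate only at the last index of each tied score block
    block_end = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    precision = tp[block_end] / (tp[block_end] + fp[block_end])
    recall = tp[block_end] / n1
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def brier(scores, labels) -> float:
    """Mean squared error of the probability forecast."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if np.any(scores < 0.0) or np.any(scores > 1.0):
        raise DomainError("Brier scores require probabilities in [0, 1]")
    return float(np.mean((scores - labels) ** 2))


def metrics_report(scores, labels, threshold: float = 0.5) -> dict:
    """Full report at a threshold: counting metrics + AUCs + Brier.

    roc_auc is ``None`` (with a reason) when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    cm = confusion(labels, (scores >= threshold).astype(np.int64))
    report = {"n": cm.n, "threshold": float(threshold)}
    report.update(basic_metrics(cm))
    report["confusion"] = {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
    one_class = len(set(labels.tolist())) < 2
    report["roc_auc"] = None if one_class else roc_auc(scores, labels)
    if one_class:
        report["roc_auc_reason"] = "single class in labels"
    report["pr_auc"] = None if (labels == 1).sum() == 0 else pr_auc(scores, labels)
    report["brier"] = brier(scores, labels)
    prevalence = float((labels == 1).mean())
    report["prevalence"] = prevalence
    report["imbalance_flag"] = bool(
        min(prevalence, 1.0 - prevalence) < IMBALANCE_FLAG_PREVALENCE
    )
    return report


# ---------------------------------------------------------------------------
# classical-classifier benchmark
# ---------------------------------------------------------------------------

def _classical_model_builders(seed: int) -> dict[str, Callable]:
    from sklearn.ensemble import (
        AdaBoostClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    builders: dict[str, Callable] = {
        "logistic_regression": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "svm_rbf": lambda: SVC(kernel="rbf", probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "gaussian_nb": lambda: GaussianNB(),
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
    }

    def _lightgbm():
        import lightgbm

        return lightgbm.LGBMClassifier(random_state=seed, verbose=-1)

    def _xgboost():
        import xgboost

        return xgboost.XGBClassifier(random_state=seed, eval_metric="logloss")

    builders["lightgbm"] = _lightgbm
    builders["xgboost"] = _xgboost
    return builders


def benchmark_classical(
    x_train: np.ndarray,
    y_train,
    x_test: np.ndarray,
    y_test,
    seed: int = 42,
    threshold: float = 0.5,
    models: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit the ten classical families on train-scaled features; report metrics.

    One row per attempted model with a ``status`` column (``ok`` or
    ``skipped: <reason>``); a missing optional back-end logs a warning.
    """
    y_train = np.asarray(y_train, dtype=np.int64)
    y_test = np.asarray(y_test, dtype=np.int64)
    if x_train.shape[1] != x_test.shape[1]:
        raise ContractError("train/test feature dimensions differ")
    if len(set(y_train.tolist())) < 2:
        raise ContractError("training data must contain both classes")
    scaler = fit_scaler(x_train)
    xtr = scaler.transform(x_train)
    xte = scaler.transform(x_test)
    builders = _classical_model_builders(seed)
    names = list(models) if models is not None else list(builders)

    rows = []
    for name in names:
        if name not in builders:
            raise ContractError(f"unknown model {name!r}; known: {sorted(builders)}")
        row: dict = {"model": name, "seed": seed}
        try:
            clf = builders[name]()
        except ImportError as exc:
            logger.warning("skipping %s: back-end unavailable (%s)", name, exc)
            row["status"] = f"skipped: {exc}"
            rows.append(row)
            continue
        clf.fit(xtr, y_train)
        prob = clf.predict_proba(xte)[:, 1]
        row.update(metrics_report(prob, y_test, threshold))
        row["status"] = "ok"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leave-one-dataset-out
# ---------------------------------------------------------------------------

def _matrix_hash(matrix: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\t".join(matrix.sample_ids).encode())
    h.update("\t".join(matrix.gene_ids).encode())
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()


@dataclass
class LodoCohortResult:
    cohort: str
    training_cohorts: list[str]
    training_sample_ids: list[str]
    training_matrix_hash: str
    panel_genes: list[str]
    youden_threshold: float
    metrics_default: dict
    metrics_youden: dict
    notes: list[str] = field(default_factory=list)


def lodo_evaluate(
    cohorts: Sequence[tuple[str, ExpressionMatrix, pd.DataFrame]],
    metabolic: GenePanel,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    fixed_panel: GenePanel | None = None,
) -> list[LodoCohortResult]:
    """Leave-one-dataset-out evaluation over named cohorts.

    For each cohort in turn: merge the *other* cohorts, batch-correct them
    with the disease covariate protected (the held-out cohort never enters
    the correction), build the functional gene pool on the corrected
    training data (or reuse ``fixed_panel``), train the ensemble, pick the
    Youden threshold on training TRS, then score the untouched held-out
    cohort and report metrics at both 0.5 and the Youden cutoff.

    Each result records the training cohort names, sample ids, and a
    sha256 hash of the exact training matrix, so hold-out exclusion is
    auditable.
    """
    if len(cohorts) < 3:
        raise ContractError("lodo_evaluate needs >= 3 cohorts")
    config = config or TrainConfig()
    from .io import labels_for  # local import to avoid cycle noise

    results: list[LodoCohortResult] = []
    for held_name, held_matrix, held_meta in cohorts:
        train_items = [(n, m, md) for n, m, md in cohorts if n != held_name]
        merged = merge_cohorts([m for _, m, _ in train_items])
        meta = pd.concat([md for _, _, md in train_items], ignore_index=True)
        labels = labels_for(merged, meta)
        batch = meta.set_index("sample_id").loc[merged.sample_ids, "cohort"].to_numpy(object)
        corrected, _dropped = combat_adjust(merged, batch, covariate=labels)

        if fixed_panel is not None:
            panel = fixed_panel
        else:
            panel, _ = build_feature_pool(corrected, labels, metabolic)
        train_input = subset_panel(corrected, panel)
        model = fit_ensemble(
            train_input, labels, panel,
            spec=spec or NetworkSpec(input_length=len(panel)), config=config,
        )
        train_trs = compute_trs(predict_ensemble(model, train_input))
        thr = youden_threshold(train_trs, labels)

        held_input = subset_panel(held_matrix, panel)
        held_labels = labels_for(held_matrix, held_meta)
        held_trs = compute_trs(predict_ensemble(model, held_input))
        notes = []
        if len(set(held_labels.tolist())) < 2:
            notes.append("held-out cohort has a single class; ranking metrics undefined")
        prev = float((held_labels == 1).mean())
        if 0.0 < min(prev, 1.0 - prev) < IMBALANCE_FLAG_PREVALENCE:
            notes.append(f"held-out prevalence {prev:.3f}: extreme class imbalance")
        results.append(
            LodoCohortResult(
                cohort=held_name,
                training_cohorts=[n for n, _, _ in train_items],
                training_sample_ids=list(merged.sample_ids),
                training_matrix_hash=_matrix_hash(merged),
                panel_genes=list(panel.gene_ids),
                youden_threshold=thr,
                metrics_default=metrics_report(held_trs, held_labels, 0.5),
                metrics_youden=metrics_report(held_trs, held_labels, thr),
                notes=notes,
            )
        )
    return results
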