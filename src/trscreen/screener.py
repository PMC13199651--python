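"""Ensemble training of the convolutional screener.

Workflow: an 80:20 stratified split sets aside a hold-out test set; the
training portion is divided into k = 5 stratified folds; for each fold a
z-score scaler is fitted on the other k-1 folds only (the held-out fold and
any later test data are transformed with those training statistics — no
leakage), a fresh network is trained with early stopping, and the five
fold-specific models are retained.  Inference averages the five predicted
probabilities per sample (the transcriptomic risk score, see
:mod:`trscreen.trs`).

The gene order along the convolution axis is the :class:`GenePanel` order;
callers are expected to subset matrices with
:func:`trscreen.io.subset_panel` before fitting or scoring.

Model bundles are plain directories: ``manifest.json`` (spec, config,
panel, seed, version), one ``fold_<i>.npz`` weight archive and one
``fold_<i>.scaler.json`` per fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BundleError, ConfigError, ContractError, MergeError
from .io import ExpressionMatrix, GenePanel
from .nn import ConvNet1D, NetworkSpec, TrainConfig, TrainingHistory, train_network

BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# stratified partitioning
# ---------------------------------------------------------------------------

def stratified_split(labels, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (train, test) preserving class proportions.

    Per class, round(fraction * n_class) samples go to training; the split
    is a deterministic function of the seed.  Both parts must be non-empty.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if not 0.0 < fraction < 1.0:
        raise ConfigError("split fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            raise ContractError(f"class {cls} has no samples")
        members = members[rng.permutation(members.size)]
        n_train = int(round(fraction * members.size))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    if not train_idx or not test_idx:
        raise ContractError("split produced an empty partition; adjust fraction")
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Assign each sample to a fold 0..k-1, balanced per class (counts +/-1)."""
    labels = np.asarray(labels, dtype=np.int64)
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.full(labels.shape[0], -1, dtype=np.int64)
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size < k:
            raise ContractError(f"class {cls} has {members.size} samples, fewer than k={k}")
        members = members[rng.permutation(members.size)]
        assignment[members] = np.arange(members.size) % k
    return assignment


# ---------------------------------------------------------------------------
# z-score scaler
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    means: np.ndarray
    sds: np.ndarray  # population sd; zero-sd features forced to 1 and flagged
    constant_features: list[int] = field(default_factory=list)

    def transform(self, x: np.ndarray) -> np.ndarray:
        """x (samples, features) -> z-scores with the stored statistics."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1] != self.means.shape[0]:
            raise ContractError(f"scaler fitted on {self.means.shape[0]} features, got {x.shape[1]}")
        return (x - self.means) / self.sds

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "constant_features": self.constant_features,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Scaler":
        return cls(
            np.asarray(payload["means"], dtype=np.float64),
            np.asarray(payload["sds"], dtype=np.float64),
            list(payload["constant_features"]),
        )


def fit_scaler(x_train: np.ndarray) -> Scaler:
    """Per-feature mean/sd (population) from training rows only."""
    x_train = np.asarray(x_train, dtype=np.float64)
    if x_train.shape[0] < 2:
        raise ContractError("fit_scaler needs >= 2 training samples")
    means = x_train.mean(axis=0)
    sds = x_train.std(axis=0)  # ddof=0
    constant = np.flatnonzero(sds == 0.0)
    sds = np.where(sds == 0.0, 1.0, sds)
    return Scaler(means, sds, constant.tolist())


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    fold_index: int
    network: ConvNet1D
    scaler: Scaler
    history: TrainingHistory


@dataclass
class EnsembleModel:
    folds: list[FoldModel]
    panel: GenePanel
    spec: NetworkSpec
    config: TrainConfig

    @property
    def k(self) -> int:
        return len(self.folds)


def build_network(spec: NetworkSpec, seed: int) -> ConvNet1D:
    """Deterministically initialized, untrained network for ``spec``."""
    return ConvNet1D(spec, seed)


def fit_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    spec: NetworkSpec,
    config: TrainConfig,
    fold_index: int,
    scaler: Scaler,
    seed: int,
) -> FoldModel:
    """Train one fold model on already-scaled data."""
    net = build_network(spec, seed)
    history = train_network(net, x_train, y_train, x_val, y_val, config, seed)
    return FoldModel(fold_index=fold_index, network=net, scaler=scaler, history=history)


def _panel_values(matrix: ExpressionMatrix, panel: GenePanel) -> np.ndarray:
    """samples x features array in panel order; all panel genes must be present."""
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in panel.gene_ids if g not in pos]
    if missing:
        raise MergeError(f"panel genes absent from matrix: {missing}")
    return matrix.values[[pos[g] for g in panel.gene_ids]].T


def fit_ensemble(
    matrix: ExpressionMatrix,
    labels,
    panel: GenePanel,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
) -> EnsembleModel:
    """Stratified k-fold training of the screener ensemble.

    ``matrix`` holds the samples to cross-validate (typically the 80%
    training portion).  Each fold's scaler comes from its k-1 training
    folds only.  Per-fold RNG streams are spawned deterministically from
    ``config.seed``.
    """
    config = config or TrainConfig()
    config.validate()
    spec = spec or NetworkSpec(input_length=len(panel))
    if spec.input_length != len(panel):
        raise ConfigError(f"spec.input_length {spec.input_length} != panel size {len(panel)}")
    labels = np.asarray(labels, dtype=np.int64)
    x_all = _panel_values(matrix, panel)
    assignment = stratified_folds(labels, config.k_folds, config.seed)
    fold_seeds = np.random.SeedSequence(config.seed).generate_state(config.k_folds) % (2**31)

    folds: list[FoldModel] = []
    for fold in range(config.k_folds):
        val_mask = assignment == fold
        train_mask = ~val_mask
        scaler = fit_scaler(x_all[train_mask])
        x_train = scaler.transform(x_all[train_mask]).astype(np.float32)
        x_val = scaler.transform(x_all[val_mask]).astype(np.float32)
        folds.append(
            fit_fold(
                x_train, labels[train_mask], x_val, labels[val_mask],
                spec, config, fold, scaler, int(fold_seeds[fold]),
            )
        )
    return EnsembleModel(folds=folds, panel=panel, spec=spec, config=config)


def predict_ensemble(model: EnsembleModel, matrix: ExpressionMatrix) -> np.ndarray:
    """Fold-probability matrix (k x n_samples); each row uses its own scaler."""
    x = _panel_values(matrix, model.panel)
    probs = np.empty((model.k, x.shape[0]), dtype=np.float64)
    for i, fold in enumerate(model.folds):
        probs[i] = fold.network.predict(fold.scaler.transform(x).astype(np.float32))
    return probs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_ensemble(model: EnsembleModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "k_folds": model.k,
        "panel": {"name": model.panel.name, "gene_ids": model.panel.gene_ids},
        "spec": model.spec.to_dict(),
        "config": model.config.to_dict(),
        "seed": model.config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    for fold in model.folds:
        np.savez(out / f"fold_{fold.fold_index}.npz", **fold.network.params)
        payload = {
            "scaler": fold.scaler.to_dict(),
            "history": {
                "train_loss": fold.history.train_loss,
                "train_accuracy": fold.history.train_accuracy,
                "val_loss": fold.history.val_loss,
                "val_accuracy": fold.history.val_accuracy,
                "learning_rate": fold.history.learning_rate,
                "stopped_epoch": fold.history.stopped_epoch,
                "best_epoch": fold.history.best_epoch,
            },
        }
        (out / f"fold_{fold.fold_index}.scaler.json").write_text(
            json.dumps(payload), encoding="utf-8"
        )


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"no manifest.json in {src}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    if manifest.get("bundle_version") != BUNDLE_VERSION:
        raise BundleError(
            f"bundle version {manifest.get('bundle_version')} != supported {BUNDLE_VERSION}"
        )
    panel = GenePanel(manifest["panel"]["gene_ids"], name=manifest["panel"]["name"])
    spec = NetworkSpec(**manifest["spec"])
    config = TrainConfig(**manifest["config"])
    folds: list[FoldModel] = []
    for i in range(manifest["k_folds"]):
        wpath = src / f"fold_{i}.npz"
        spath = src / f"fold_{i}.scaler.json"
        if not wpath.exists() or not spath.exists():
            raise BundleError(f"bundle missing files for fold {i}")
        net = ConvNet1D(spec, seed=config.seed)
        with np.load(wpath) as archive:
            net.set_weights({k: archive[k] for k in archive.files})
        payload = json.loads(spath.read_text(encoding="utf-8"))
        scaler = Scaler.from_dict(payload["scaler"])
        hist = TrainingHistory(**payload["history"])
        folds.append(FoldModel(fold_index=i, network=net, scaler=scaler, history=hist))
    return EnsembleModel(folds=folds, panel=panel, spec=spec, config=config)
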