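"""Synthetic multicohort expression data with known ground truth.

The generator emulates the structure of merged public CRC cohorts: several
cohorts measured on distinct platforms, each contributing an additive
per-gene offset and a multiplicative per-gene residual scale (exactly the
location/scale model the empirical-Bayes batch correction assumes), binary
disease labels with cohort-specific prevalence, and a designated subset of
class-informative genes whose mean is shifted in metastatic (class 1)
samples *before* batch effects are applied — so biological signal is
confounded with batch, the realistic hard case.

Model, on the log2 scale:

    x_gs = b_g + e * 1[s in class 1, g informative]
           + gamma_gc(s) + exp(sigma_c(s,g)) * eps_gs

with gene baselines b_g ~ N(8, 2) (typical log2 array intensity),
offsets gamma_gc ~ N(0, batch_shift_sd), log scales ~ N(0, batch_scale_sd),
and residuals eps_gs ~ N(0, noise_sd).

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config; identical config + seed reproduces the output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, write_expression, write_metadata

BASELINE_MEAN = 8.0  # log2-scale location of gene baselines
BASELINE_SD = 2.0


@dataclass
class GeneratorConfig:
    n_cohorts: int = 3
    samples_per_cohort: Sequence[int] = (100, 100, 100)
    prevalence_per_cohort: Sequence[float] = (0.5, 0.5, 0.5)
    n_genes: int = 1000
    n_informative: int = 50
    effect_size: float = 1.5
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    noise_sd: float = 1.0
    seed: int = 42

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ConfigError("n_cohorts must be positive")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ConfigError("samples_per_cohort length must equal n_cohorts")
        if len(self.prevalence_per_cohort) != self.n_cohorts:
            raise ConfigError("prevalence_per_cohort length must equal n_cohorts")
        if any(n < 1 for n in self.samples_per_cohort):
            raise ConfigError("samples_per_cohort entries must be positive")
        if any(not (0.0 <= p <= 1.0) for p in self.prevalence_per_cohort):
            raise ConfigError("prevalence_per_cohort entries must lie in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ConfigError("n_informative must satisfy 0 <= n_informative <= n_genes")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class GeneratorTruth:
    informative_genes: list[str]
    per_cohort_offsets: np.ndarray  # genes x cohorts additive
    per_cohort_scales: np.ndarray   # genes x cohorts multiplicative (on residual)
    true_labels: dict[str, int]
    cohort_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_genes": self.informative_genes,
            "per_cohort_offsets": self.per_cohort_offsets.tolist(),
            "per_cohort_scales": self.per_cohort_scales.tolist(),
            "true_labels": self.true_labels,
            "cohort_names": self.cohort_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            payload["informative_genes"],
            np.asarray(payload["per_cohort_offsets"]),
            np.asarray(payload["per_cohort_scales"]),
            {k: int(v) for k, v in payload["true_labels"].items()},
            payload.get("cohort_names", []),
        )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_multicohort(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneratorTruth]:
    """Generate a multicohort dataset with known batch effects and truth.

    Per-cohort positive counts are deterministic, ``round(prevalence * n)``,
    so small cohorts hit their nominal prevalence exactly; which samples are
    positive is randomized.  Returns (expression, metadata, truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    informative_idx = rng.choice(config.n_genes, size=config.n_informative, replace=False)
    informative_idx.sort()
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    offsets = rng.normal(0.0, config.batch_shift_sd, size=(config.n_genes, config.n_cohorts))
    scales = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_genes, config.n_cohorts)))

    cohort_names = [f"cohort{c + 1}" for c in range(config.n_cohorts)]
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    cohort_col: list[str] = []
    labels: list[int] = []
    for c, (n_c, prev) in enumerate(zip(config.samples_per_cohort, config.prevalence_per_cohort)):
        n_pos = int(round(prev * n_c))
        y = np.zeros(n_c, dtype=np.int64)
        y[rng.choice(n_c, size=n_pos, replace=False)] = 1
        x = np.tile(baselines[:, None], (1, n_c))
        x[informative_idx[:, None], np.flatnonzero(y == 1)[None, :]] += config.effect_size
        eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_c))
        x += offsets[:, [c]] + scales[:, [c]] * eps
        blocks.append(x)
        sample_ids.extend(f"{cohort_names[c]}_S{i + 1:04d}" for i in range(n_c))
        cohort_col.extend([cohort_names[c]] * n_c)
        labels.extend(int(v) for v in y)

    matrix = ExpressionMatrix(genes, sample_ids, np.concatenate(blocks, axis=1))
    metadata = pd.DataFrame({"sample_id": sample_ids, "cohort": cohort_col, "label": labels})
    truth = GeneratorTruth(
        informative_genes=[genes[i] for i in informative_idx],
        per_cohort_offsets=offsets,
        per_cohort_scales=scales,
        true_labels=dict(zip(sample_ids, labels)),
        cohort_names=cohort_names,
    )
    return matrix, metadata, truth


def generate_separable_binary(
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    seed: int,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneratorTruth]:
    """Single-cohort, batch-free dataset with balanced labels (|n1-n0| <= 1).

    A convenience front end to :func:`generate_multicohort` for classifier
    calibration experiments.
    """
    if n_informative > n_features:
        raise ConfigError("n_informative must not exceed n_features")
    config = GeneratorConfig(
        n_cohorts=1,
        samples_per_cohort=(n_samples,),
        prevalence_per_cohort=(0.5,),
        n_genes=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_multicohort(config)


def write_dataset(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    truth: GeneratorTruth,
) -> dict[str, Path]:
    """Write expression TSV, metadata TSV and truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_expression(matrix, paths["expression"])
    write_metadata(metadata, paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
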