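"""Reading, validation, and harmonization of multicohort expression data.

Containers
----------
:class:`ExpressionMatrix`
    genes x samples numeric matrix (log2 scale after transformation) with
    ordered, unique gene and sample identifiers.
:class:`GenePanel`
    an ordered, unique gene list; its order defines the convolution axis of
    the downstream classifier, so it is part of the model contract.

Sample metadata travels as a :class:`pandas.DataFrame` with columns
``sample_id``, ``cohort`` (the batch variable) and ``label``
(0 = primary, 1 = metastasis, NaN = unknown).

Gene identifiers are matched as exact strings; callers must map probes or
aliases to a common symbol space upstream.  Duplicate gene rows within one
file are collapsed by keeping the row with the highest mean expression (the
common array convention); removals are logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError, FormatError, MergeError

logger = logging.getLogger(__name__)

REQUIRED_META_COLUMNS = ("sample_id", "cohort", "label")


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in ExpressionMatrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in ExpressionMatrix")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite values in ExpressionMatrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=np.float64))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise ContractError(f"unknown sample id {exc.args[0]!r}") from None
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), self.values.copy())


@dataclass
class GenePanel:
    gene_ids: list[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.gene_ids:
            raise FormatError(f"gene panel {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError(f"gene panel {self.name!r} contains duplicate entries")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed to the row with the highest mean.
    Non-numeric cells raise :class:`FormatError` naming the offending cell.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        dups = sorted({s for s in sample_header if sample_header.count(s) > 1})
        raise FormatError(f"duplicate sample ids in {path.name}: {dups}")
    # float_precision='round_trip' gives correctly-rounded parsing (exact
    # repr round-trip); keep_default_na=False so 'NA' surfaces as a parse error
    frame = pd.read_csv(
        path, sep=sep, index_col=0, keep_default_na=False, float_precision="round_trip"
    )
    values = np.empty(frame.shape, dtype=np.float64)
    for j, col in enumerate(frame.columns):
        column = frame[col]
        if np.issubdtype(column.dtype, np.number):
            values[:, j] = column.to_numpy(dtype=np.float64)
            continue
        for gene, cell in zip(frame.index, column):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell at gene {gene!r}, sample {col!r} in {path.name}"
                ) from None
        values[:, j] = [float(v) for v in column]
    gene_ids = [str(g) for g in frame.index]
    if len(set(gene_ids)) != len(gene_ids):
        full = pd.DataFrame(values, index=gene_ids, columns=frame.columns)
        means = full.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep_rows: dict[str, int] = {}
        for row in order:  # first hit in descending-mean order wins
            keep_rows.setdefault(gene_ids[row], row)
        n_dropped = len(gene_ids) - len(keep_rows)
        logger.info("collapsed %d duplicate gene rows in %s (kept max-mean row)", n_dropped, path.name)
        rows = sorted(keep_rows.values())
        gene_ids = [gene_ids[r] for r in rows]
        values = values[rows]
    return ExpressionMatrix(gene_ids, list(frame.columns), values)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV; requires sample_id, cohort, label columns.

    Labels are coerced to {0, 1} integers (missing allowed, kept as NaN);
    anything else raises :class:`FormatError`.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "cohort": str})
    missing = [c for c in REQUIRED_META_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"metadata {path.name} missing required columns {missing}; "
            f"required: {list(REQUIRED_META_COLUMNS)}"
        )
    if table["sample_id"].duplicated().any():
        dups = sorted(table.loc[table["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    labels = pd.to_numeric(table["label"], errors="coerce")
    raw_missing = table["label"].isna() | table["label"].astype(str).str.strip().isin({"", "NA", "nan"})
    bad = ~raw_missing & (~labels.isin([0, 1]) | labels.isna())
    if bad.any():
        vals = sorted(set(table.loc[bad, "label"].astype(str)))
        raise FormatError(f"labels must be 0, 1 or missing; found {vals}")
    table = table.copy()
    table["label"] = labels.where(~raw_missing).astype("Float64")
    return table


def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a plain-text gene panel, one symbol per line (blanks ignored)."""
    path = Path(path)
    genes = [line.strip() for line in path.read_text(encoding="utf-8").splitlines()]
    genes = [g for g in genes if g]
    return GenePanel(genes, name=name or path.stem)


# ---------------------------------------------------------------------------
# writers (UTF-8, tab-delimited, full float precision)
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.gene_ids) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# harmonization operations
# ---------------------------------------------------------------------------

def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their gene sets.

    The output gene order is lexicographic (a deterministic canonical order;
    required because the classifier's convolution axis must be reproducible).
    Sample columns are concatenated in input order.
    """
    if len(matrices) < 2:
        raise ContractError("merge_cohorts requires at least 2 matrices")
    common: set[str] = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise MergeError("empty gene intersection across cohorts")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        seen: set[str] = set()
        clash = next(s for s in all_samples if s in seen or seen.add(s))
        raise MergeError(f"sample id {clash!r} appears in more than one cohort")
    genes = sorted(common)
    blocks = []
    for m in matrices:
        pos = {g: i for i, g in enumerate(m.gene_ids)}
        blocks.append(m.values[[pos[g] for g in genes]])
    return ExpressionMatrix(genes, all_samples, np.concatenate(blocks, axis=1))


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> log2(v + 1); negative input values are a domain error."""
    if np.any(matrix.values < 0):
        g, s = np.argwhere(matrix.values < 0)[0]
        raise DomainError(
            f"log2p1 requires non-negative values; gene {matrix.gene_ids[g]!r}, "
            f"sample {matrix.sample_ids[s]!r} is {matrix.values[g, s]}"
        )
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), np.log2(matrix.values + 1.0))


def deduplicate_samples(
    matrices: Sequence[ExpressionMatrix], metadata: pd.DataFrame
) -> tuple[list[ExpressionMatrix], pd.DataFrame]:
    """Drop cross-cohort duplicate samples, keeping the first occurrence.

    Applied to the per-cohort matrices *before* merging (each matrix is
    internally duplicate-free; repeats occur across cohorts).  Metadata rows
    for removed samples are dropped too.  Removals are logged.
    """
    known = set(metadata["sample_id"])
    for m in matrices:
        missing = [s for s in m.sample_ids if s not in known]
        if missing:
            raise ContractError(f"metadata does not cover samples {missing[:5]}")
    seen: set[str] = set()
    out: list[ExpressionMatrix] = []
    dropped: list[str] = []
    for m in matrices:
        keep = []
        for j, s in enumerate(m.sample_ids):
            if s in seen:
                dropped.append(s)
            else:
                seen.add(s)
                keep.append(j)
        if len(keep) == len(m.sample_ids):
            out.append(m)
        else:
            out.append(
                ExpressionMatrix(
                    list(m.gene_ids), [m.sample_ids[j] for j in keep], m.values[:, keep]
                )
            )
    if dropped:
        logger.info("deduplicate_samples removed %d duplicate columns: %s",
                    len(dropped), sorted(set(dropped)))
    keep_meta = metadata[~metadata["sample_id"].duplicated(keep="first")].reset_index(drop=True)
    return out, keep_meta


def subset_panel(
    matrix: ExpressionMatrix, panel: GenePanel, on_missing: str = "error"
) -> ExpressionMatrix:
    """Restrict the matrix to panel genes, in panel order.

    The panel order defines the downstream convolution axis.  Missing panel
    genes either raise (``on_missing='error'``) or are imputed with the
    per-sample mean of the present panel genes (``'impute_mean'``).
    """
    if on_missing not in ("error", "impute_mean"):
        raise ContractError(f"on_missing must be 'error' or 'impute_mean', got {on_missing!r}")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in panel.gene_ids if g not in pos]
    if missing and on_missing == "error":
        raise MergeError(f"panel genes absent from matrix: {missing}")
    present_rows = [pos[g] for g in panel.gene_ids if g in pos]
    if not present_rows:
        raise MergeError("no panel genes present in matrix")
    col_means = matrix.values[present_rows].mean(axis=0)
    out = np.empty((len(panel), len(matrix.sample_ids)), dtype=np.float64)
    for i, g in enumerate(panel.gene_ids):
        out[i] = matrix.values[pos[g]] if g in pos else col_means
    if missing:
        logger.warning("imputed %d missing panel genes with per-sample means: %s", len(missing), missing)
    return ExpressionMatrix(list(panel.gene_ids), list(matrix.sample_ids), out)


def labels_for(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> np.ndarray:
    """Return the 0/1 label vector aligned to the matrix sample order."""
    table = metadata.set_index("sample_id")
    try:
        labels = table.loc[matrix.sample_ids, "label"]
    except KeyError as exc:
        raise ContractError(f"metadata missing sample {exc.args[0]!r}") from None
    if labels.isna().any():
        miss = list(labels.index[labels.isna()])[:5]
        raise ContractError(f"missing labels for samples {miss}")
    return labels.to_numpy(dtype=np.float64).astype(np.int64)


def cohorts_for(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> np.ndarray:
    """Return the cohort (batch) vector aligned to the matrix sample order."""
    table = metadata.set_index("sample_id")
    try:
        return table.loc[matrix.sample_ids, "cohort"].to_numpy(dtype=object)
    except KeyError as exc:
        raise ContractError(f"metadata missing sample {exc.args[0]!r}") from None
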