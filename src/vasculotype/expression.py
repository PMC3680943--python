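"""Expression data model, I/O, probe collapsing, variance filtering, row scaling.

Matrices are genes x samples on the log2 scale, tab-delimited on disk with a
leading ``gene_id`` column.  Sample annotations travel as a CSV with a fixed
column set (:data:`SAMPLE_COLUMNS`).  Missing expression values are not
supported: readers reject them.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "SAMPLE_COLUMNS",
    "collapse_probes",
    "iqr",
    "iqr_filter",
    "read_gene_set",
    "read_gmt",
    "read_matrix",
    "read_samples",
    "row_zscore",
    "validate_samples",
    "write_matrix",
    "write_samples",
]

#: Canonical column order of the sample annotation table.
SAMPLE_COLUMNS = [
    "sample_id",
    "tissue",
    "mvd_class",
    "subtype",
    "recurrence",
    "er_status",
    "her2_status",
    "node_status",
    "grade",
    "tumor_size",
]

TISSUES = {"normal_vasculature", "tumor_vasculature"}


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {axis} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples grid of log2 intensities with ordered unique ids."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("expression values contain NaN/inf; missing data unsupported")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(frame.index), tuple(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        idx = [pos[g] for g in wanted]
        return ExpressionMatrix(self.values[idx], tuple(wanted), self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in wanted]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, tuple(wanted))


# ---------------------------------------------------------------------------
# Matrix I/O


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited matrix (header of sample ids, first column gene ids)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "gene_id":
            raise FormatError(f"{path}: first header cell must be 'gene_id', got {header[:1]!r}")
        sample_ids = header[1:]
        if not sample_ids:
            raise FormatError(f"{path}: no sample columns")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected {len(header)}"
                )
            gene_ids.append(rec[0])
            parsed = []
            for col, cell in enumerate(rec[1:], start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at line {lineno}, "
                        f"column {header[col]!r}: {cell!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    matrix = ExpressionMatrix(np.array(rows, dtype=float), tuple(gene_ids), tuple(sample_ids))
    return matrix


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample annotations


def validate_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample annotation table and normalise NA handling."""
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise FormatError(f"annotation table missing columns: {missing_cols}")
    table = table[SAMPLE_COLUMNS].copy()
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    bad_tissue = set(table["tissue"].dropna()) - TISSUES
    if bad_tissue:
        raise FormatError(f"unknown tissue values: {sorted(bad_tissue)}")
    normal = table["tissue"] == "normal_vasculature"
    for col in ("subtype", "recurrence"):
        if table.loc[normal, col].notna().any():
            raise FormatError(f"{col} must be NA for normal_vasculature samples")
    return table


def read_samples(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"sample_id": str}, na_values=["NA", ""],
                        keep_default_na=True)
    return validate_samples(table)


def write_samples(table: pd.DataFrame, path: str | Path) -> None:
    validate_samples(table).to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Gene sets


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene set, one symbol per line (blank lines ignored)."""
    path = Path(path)
    symbols = [line.strip() for line in path.read_text(encoding="utf-8").splitlines()]
    symbols = [s for s in symbols if s]
    return GeneSet(name or path.stem, frozenset(symbols))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: tab-delimited lines of name, description, members..."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        sets.append(GeneSet(parts[0], frozenset(p for p in parts[2:] if p)))
    return sets


# ---------------------------------------------------------------------------
# Row statistics and filters


def iqr(values: Sequence[float] | np.ndarray) -> float:
    """Interquartile range under the 1+(n-1)p linear-interpolation convention."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("iqr of empty input")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return float(q3 - q1)


def _row_iqrs(values: np.ndarray) -> np.ndarray:
    q1 = np.quantile(values, 0.25, axis=1)
    q3 = np.quantile(values, 0.75, axis=1)
    return q3 - q1


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probes to gene symbols, keeping the probe with the largest IQR.

    Exact IQR ties are broken by lexicographically smallest probe id.  Output
    rows are ordered by first appearance of each symbol in the input.
    """
    unmapped = [p for p in matrix.gene_ids if p not in probe_map]
    if unmapped:
        raise FormatError(f"unmapped probes: {unmapped}")
    iqrs = _row_iqrs(matrix.values)
    best: dict[str, tuple[float, str, int]] = {}
    order: list[str] = []
    for i, probe in enumerate(matrix.gene_ids):
        symbol = probe_map[probe]
        if symbol not in best:
            order.append(symbol)
            best[symbol] = (iqrs[i], probe, i)
        else:
            cur_iqr, cur_probe, _ = best[symbol]
            if (iqrs[i], ) > (cur_iqr, ) or (iqrs[i] == cur_iqr and probe < cur_probe):
                best[symbol] = (iqrs[i], probe, i)
    idx = [best[s][2] for s in order]
    return ExpressionMatrix(matrix.values[idx], tuple(order), matrix.sample_ids)


def iqr_filter(matrix: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep rows with IQR strictly greater than ``threshold`` (row order kept)."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    keep = _row_iqrs(matrix.values) > threshold
    if not keep.any():
        raise ValidationError(
            f"IQR filter at {threshold} removed every row; lower the threshold"
        )
    kept_ids = tuple(g for g, k in zip(matrix.gene_ids, keep) if k)
    return ExpressionMatrix(matrix.values[keep], kept_ids, matrix.sample_ids)


def row_zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each row to mean 0, sample sd 1 (ddof=1); constant rows become 0."""
    if matrix.n_samples < 2:
        raise ValidationError("row_zscore needs >= 2 samples")
    means = matrix.values.mean(axis=1, keepdims=True)
    sds = matrix.values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to zeros",
            stacklevel=2,
        )
    safe = np.where(sds == 0, 1.0, sds)
    z = (matrix.values - means) / safe
    z[constant, :] = 0.0
    return ExpressionMatrix(z, matrix.gene_ids, matrix.sample_ids)
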