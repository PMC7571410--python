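"""Reading and writing expression matrices, marker sets, labels and results.

The canonical interchange format is a dense TSV with gene ids in the first
column and a header row of cell ids.  MatrixMarket coordinate files are
supported for conventionally sparse scRNA-seq matrices; a ``<stem>.rows.txt``
and ``<stem>.cols.txt`` file alongside the ``.mtx`` carry the ids.

Matrix orientation is fixed as genes-in-rows, cells-in-columns.  Readers
transpose only when asked explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "MarkerSet",
    "LabelVector",
    "DataIOError",
    "MissingFileError",
    "NonNumericValueError",
    "DuplicateIdError",
    "NegativeValueError",
    "MalformedFileError",
    "read_expression",
    "write_expression",
    "read_markers",
    "write_markers",
    "read_labels",
    "write_labels",
    "write_factorization",
    "read_matrix_tsv",
]

#: significant digits used when writing matrices
_WRITE_FMT = "%.10g"


class DataIOError(Exception):
    """Base class for input/output validation failures."""


class MissingFileError(DataIOError):
    """A required file does not exist."""


class NonNumericValueError(DataIOError):
    """A matrix cell could not be parsed as a number."""


class DuplicateIdError(DataIOError):
    """Gene or cell identifiers are not unique within their axis."""


class NegativeValueError(DataIOError):
    """The expression matrix contains a negative entry."""


class MalformedFileError(DataIOError):
    """A marker or label file violates its expected layout."""


@dataclass
class ExpressionMatrix:
    """A nonnegative gene-by-cell expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ``(m, n)`` array, genes in rows and cells in columns.  Entries
        may be raw counts or any normalized unit (CPM, FPKM, RPKM, TPM);
        the unit is recorded as free text in ``unit_tag``.
    gene_ids, cell_ids
        Unique string identifiers for the rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit_tag: str = ""
    #: row-submatrices (e.g. selected marker rows) may have a single gene
    is_submatrix: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataIOError(f"expected a 2-d matrix, got ndim={self.values.ndim}")
        m, n = self.values.shape
        min_genes = 1 if self.is_submatrix else 2
        if m < min_genes or n < 2:
            raise DataIOError(f"matrix must be at least {min_genes}x2, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise DataIOError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.cell_ids) != n:
            raise DataIOError(f"{len(self.cell_ids)} cell ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise DuplicateIdError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise DuplicateIdError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise DataIOError("matrix contains NaN or Inf")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise NegativeValueError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-submatrix over *gene_ids*, preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows, :], list(gene_ids), list(self.cell_ids), self.unit_tag,
            is_submatrix=True,
        )


@dataclass
class MarkerSet:
    """Ordered mapping from a known cell-group label to its marker gene ids."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise DataIOError("marker set must contain at least one group")
        if not any(len(g) >= 1 for g in self.groups.values()):
            raise DataIOError("marker set must contain at least one gene")

    def all_genes(self) -> list[str]:
        """Union of all groups' genes, ordered by first appearance."""
        seen: dict[str, None] = {}
        for genes in self.groups.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class LabelVector:
    """Cluster assignments for n cells, aligned to an ExpressionMatrix."""

    labels: list
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) == 0:
            raise DataIOError("empty label vector")
        if self.cell_ids is not None and len(self.cell_ids) != len(self.labels):
            raise DataIOError("cell_ids and labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels)


def _check_exists(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    return path


def read_matrix_tsv(path, sep: str = "\t") -> tuple[np.ndarray, list[str], list[str]]:
    """Parse a dense id-annotated matrix; returns (values, row_ids, col_ids)."""
    path = _check_exists(Path(path))
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise NonNumericValueError(f"{path}: {exc}") from exc
    if len(set(row_ids)) != len(row_ids) or len(set(col_ids)) != len(col_ids):
        raise DuplicateIdError(f"{path}: duplicate row or column ids")
    return values, row_ids, col_ids


def read_expression(
    path,
    format: str | None = None,
    *,
    transpose: bool = False,
    unit_tag: str = "",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket MTX.

    For MTX input the files ``<stem>.rows.txt`` and ``<stem>.cols.txt`` must
    sit beside the matrix file, one id per line.  Negative entries are
    rejected, never clamped.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format not in ("tsv", "csv", "mtx"):
        raise ValueError(f"unknown format {format!r}")
    if format == "mtx":
        _check_exists(path)
        stem = path.with_suffix("")
        rows_file = _check_exists(stem.with_suffix(".rows.txt"))
        cols_file = _check_exists(stem.with_suffix(".cols.txt"))
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        gene_ids = rows_file.read_text().split()
        cell_ids = cols_file.read_text().split()
    else:
        sep = "\t" if format == "tsv" else ","
        values, gene_ids, cell_ids = read_matrix_tsv(path, sep=sep)
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, cell_ids, unit_tag)


def write_expression(x: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write an expression matrix as TSV/CSV or MatrixMarket with id files."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(x.values))
        stem = path.with_suffix("")
        stem.with_suffix(".rows.txt").write_text("\n".join(x.gene_ids) + "\n")
        stem.with_suffix(".cols.txt").write_text("\n".join(x.cell_ids) + "\n")
    else:
        sep = "\t" if format == "tsv" else ","
        _write_matrix(x.values, x.gene_ids, x.cell_ids, path, sep=sep)


def _write_matrix(values, row_ids, col_ids, path, sep: str = "\t", index_label: str = "id") -> None:
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.to_csv(path, sep=sep, float_format=_WRITE_FMT, index_label=index_label)


def read_markers(path) -> MarkerSet:
    """Read a marker file: 2-column TSV (group, gene) or JSON {group: [genes]}.

    Group order follows first appearance in the file.  Duplicated
    (group, gene) pairs are dropped with a warning.
    """
    path = _check_exists(Path(path))
    text = path.read_text().strip()
    if not text:
        raise MalformedFileError(f"{path}: empty marker file")
    groups: dict[str, list[str]] = {}
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        if not isinstance(obj, dict):
            raise MalformedFileError(f"{path}: JSON marker file must be an object")
        for group, genes in obj.items():
            if not isinstance(genes, list):
                raise MalformedFileError(f"{path}: group {group!r} is not a list")
            groups[str(group)] = []
            for g in genes:
                if g in groups[str(group)]:
                    warnings.warn(f"duplicate marker ({group}, {g}) ignored")
                else:
                    groups[str(group)].append(str(g))
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise MalformedFileError(f"{path}:{lineno}: expected 'group<TAB>gene'")
            group, gene = parts
            bucket = groups.setdefault(group, [])
            if gene in bucket:
                warnings.warn(f"duplicate marker ({group}, {gene}) ignored")
            else:
                bucket.append(gene)
    return MarkerSet(groups)


def write_markers(markers: MarkerSet, path) -> None:
    lines = [f"{group}\t{gene}" for group, genes in markers.groups.items() for gene in genes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path) -> LabelVector:
    """Read a 2-column TSV of (cell_id, label)."""
    path = _check_exists(Path(path))
    cell_ids: list[str] = []
    labels: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MalformedFileError(f"{path}:{lineno}: expected 'cell_id<TAB>label'")
        cell_ids.append(parts[0])
        labels.append(parts[1])
    if not labels:
        raise MalformedFileError(f"{path}: empty label file")
    return LabelVector(labels, cell_ids)


def write_labels(labels: LabelVector, path) -> None:
    ids = labels.cell_ids or [f"cell{i}" for i in range(len(labels))]
    Path(path).write_text(
        "\n".join(f"{c}\t{l}" for c, l in zip(ids, labels.labels)) + "\n"
    )


def write_factorization(result, dir) -> None:
    """Persist a factorization: W.tsv, H.tsv, S.tsv, objective_trace.tsv, params.json.

    The S matrix is written even when it is identically zero, so that a
    result directory is always complete.  Values round-trip through
    :func:`read_matrix_tsv` at the printed precision.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    k = result.W.shape[1]
    m = result.W.shape[0]
    n = result.H.shape[1]
    gene_ids = getattr(result, "gene_ids", None) or [f"gene{i}" for i in range(m)]
    cell_ids = getattr(result, "cell_ids", None) or [f"cell{j}" for j in range(n)]
    meta = [f"metagene{j + 1}" for j in range(k)]
    _write_matrix(result.W, gene_ids, meta, dir / "W.tsv")
    _write_matrix(result.H, meta, cell_ids, dir / "H.tsv")
    S = result.S if result.S is not None else np.zeros((m, n))
    _write_matrix(S, gene_ids, cell_ids, dir / "S.tsv")
    trace = pd.DataFrame(
        {"iteration": np.arange(len(result.objective_trace)),
         "objective": result.objective_trace}
    )
    trace.to_csv(dir / "objective_trace.tsv", sep="\t", index=False,
                 float_format=_WRITE_FMT)
    params = dict(result.params)
    params.update(n_iter=result.n_iter, converged=bool(result.converged))
    (dir / "params.json").write_text(json.dumps(params, indent=2, default=str) + "\n")
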