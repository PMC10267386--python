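"""Labeled mutation-matrix I/O and per-dataset characterization.

A mutation matrix is a dense samples-by-genes table of numeric variant
calls: SNV-style tables hold small non-negative integer counts (most cells
zero), CNV-style tables hold signed gain/loss values and are considerably
denser.  Two interchange formats are supported: a dense TSV with a header
row of gene labels and a header column of sample labels, and MatrixMarket
coordinate files (labels are not representable in MatrixMarket and are
regenerated on read).

`profile_dataset` computes the characterization statistics used throughout
the benchmark reports: size, non-zero count, sparsity (percentage of
non-zero cells — higher means denser), row count, rows/columns ratio, the
operator 1-norm (maximum absolute column sum), the spectral norm (largest
singular value), numerical rank, and optionally the share of positive
entries among the non-zeros (meaningful for signed CNV data).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .errors import FormatError, ParseError

__all__ = [
    "MutationMatrix",
    "DatasetProfile",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_matrix_market",
    "write_matrix_market",
    "profile_dataset",
    "round_half_up",
]


def default_row_labels(m: int) -> list[str]:
    return [f"S{i}" for i in range(m)]


def default_col_labels(n: int) -> list[str]:
    return [f"G{j}" for j in range(n)]


@dataclass
class MutationMatrix:
    """A labeled m-by-n numeric samples-by-genes matrix.

    Invariants (checked on construction): both dimensions positive, labels
    unique within their axis and free of tab/newline characters, every cell
    finite.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_labels = [str(s) for s in self.row_labels]
        self.col_labels = [str(s) for s in self.col_labels]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        m, n = self.values.shape
        if m == 0 or n == 0:
            raise ValueError("matrix must have at least one row and one column")
        if len(self.row_labels) != m or len(self.col_labels) != n:
            raise ValueError(
                f"label counts ({len(self.row_labels)}, {len(self.col_labels)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for axis, labels in (("row", self.row_labels), ("column", self.col_labels)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{axis} labels are not unique")
            if any("\t" in s or "\n" in s for s in labels):
                raise ValueError(f"{axis} labels must not contain tabs or newlines")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix cells must all be finite")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    def equals(self, other: "MutationMatrix", check_labels: bool = True) -> bool:
        """Cell-for-cell equality (dtype-insensitive), optionally labels too."""
        if self.shape != other.shape:
            return False
        if check_labels and (
            self.row_labels != other.row_labels or self.col_labels != other.col_labels
        ):
            return False
        return bool(np.array_equal(self.values, other.values))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - thin wrapper
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return self.equals(other)


@dataclass
class DatasetProfile:
    """Characterization statistics for one dataset (one benchmark-table row)."""

    dataset_size: int
    nnz: int
    sparsity_pct: float
    rows: int
    rows_over_cols_pct: float
    file_size_bytes: int | None
    l1_norm: float
    l2_norm: float
    rank: int
    nonneg_ratio_pct: float | None = None

    FIELDS = (
        "dataset_size",
        "nnz",
        "sparsity_pct",
        "rows",
        "rows_over_cols_pct",
        "file_size_bytes",
        "l1_norm",
        "l2_norm",
        "rank",
        "nonneg_ratio_pct",
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Round-half-up to `ndigits` decimals, as the benchmark tables print."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _parse_cell(token: str) -> int | float:
    s = token.strip()
    if not s:
        return 0  # sparse-by-omission: empty cell means no call
    try:
        return int(s)
    except ValueError:
        return float(s)  # may raise ValueError; caller annotates position


def read_dense_tsv(path: str | Path) -> MutationMatrix:
    """Read a dense TSV table: header row = gene labels, header column = samples.

    Empty cells read as 0.  Integer tables are preserved exactly (int64);
    any real-valued cell switches the whole matrix to float64.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_labels = header[1:]
    n = len(col_labels)
    if n == 0:
        raise FormatError(f"{path}: header row has no column labels")
    row_labels: list[str] = []
    rows: list[list[int | float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {n + 1} tab-separated fields, "
                f"found {len(parts)}"
            )
        row_labels.append(parts[0])
        cells: list[int | float] = []
        for j, token in enumerate(parts[1:]):
            try:
                cells.append(_parse_cell(token))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {token!r} at row {parts[0]!r}, "
                    f"column {col_labels[j]!r}"
                ) from None
        rows.append(cells)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    all_int = all(isinstance(c, int) for row in rows for c in row)
    values = np.array(rows, dtype=np.int64 if all_int else np.float64)
    return MutationMatrix(row_labels, col_labels, values)


def _format_cell(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))  # shortest round-trip representation


def write_dense_tsv(M: MutationMatrix, path: str | Path) -> None:
    """Write the dense TSV form; byte-deterministic for identical input."""
    lines = ["\t".join(["", *M.col_labels])]
    for label, row in zip(M.row_labels, M.values):
        lines.append("\t".join([label, *(_format_cell(v) for v in row)]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_matrix_market(path: str | Path) -> MutationMatrix:
    """Read a MatrixMarket coordinate file (1-based on disk, 0-based in memory).

    MatrixMarket carries no labels; default ``S{i}``/``G{j}`` labels are
    attached.
    """
    try:
        A = scipy.io.mmread(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable MatrixMarket file: {exc}") from exc
    if scipy.sparse.issparse(A):
        A = A.toarray()
    A = np.asarray(A)
    if A.dtype.kind == "f" and np.all(A == np.round(A)) and np.all(np.abs(A) < 2**53):
        # integer-field files come back as floats from some writers
        info = scipy.io.mminfo(str(path))
        if info[5] == "integer":
            A = A.astype(np.int64)
    m, n = A.shape
    return MutationMatrix(default_row_labels(m), default_col_labels(n), A)


def write_matrix_market(M: MutationMatrix, path: str | Path) -> None:
    """Write MatrixMarket coordinate format ("integer"/"real general", 1-based).

    Labels are not representable in MatrixMarket and are dropped.
    """
    A = M.values
    field = "integer" if A.dtype.kind in "iu" else "real"
    coo = scipy.sparse.coo_matrix(A)
    scipy.io.mmwrite(str(path), coo, field=field, precision=17)


def profile_dataset(
    M: MutationMatrix,
    file_size_bytes: int | None = None,
    include_nonneg_ratio: bool = False,
) -> DatasetProfile:
    """Compute the per-dataset characterization row.

    Norm conventions: ``l1_norm`` is the matrix operator 1-norm (maximum
    absolute column sum), ``l2_norm`` the spectral norm (largest singular
    value), and ``rank`` the numerical rank with tolerance
    ``max(m, n) * eps * sigma_max``.
    """
    A = M.values
    m, n = A.shape
    nnz = M.nnz
    size = m * n
    l1 = float(np.max(np.abs(A).sum(axis=0))) if nnz else 0.0
    if nnz:
        svals = np.linalg.svd(A.astype(np.float64), compute_uv=False)
        l2 = float(svals[0])
        tol = max(m, n) * np.finfo(np.float64).eps * l2
        rank = int(np.count_nonzero(svals > tol))
    else:
        l2 = 0.0
        rank = 0
    nonneg = None
    if include_nonneg_ratio:
        nonneg = 100.0 * float(np.count_nonzero(A > 0)) / nnz if nnz else 0.0
    return DatasetProfile(
        dataset_size=size,
        nnz=nnz,
        sparsity_pct=100.0 * nnz / size,
        rows=m,
        rows_over_cols_pct=100.0 * m / n,
        file_size_bytes=file_size_bytes,
        l1_norm=l1,
        l2_norm=l2,
        rank=rank,
        nonneg_ratio_pct=nonneg,
    )
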