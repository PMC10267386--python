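"""The three in-memory sparse encodings: COO triplets, CSC and CSR.

Encoders traverse the dense matrix in the target format's canonical order
(row-major for COO and CSR, column-major for CSC); decoders walk the
compressed structure's own access units — one triplet at a time for COO
(the format exposes no block structure), one pointer-delimited column or
row slice at a time for CSC/CSR.  Explicit zeros are dropped at encode
time; duplicate coordinates are an integrity error, never summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError
from .matrixio import MutationMatrix, default_col_labels, default_row_labels

__all__ = [
    "TripletSet",
    "CSCForm",
    "CSRForm",
    "coo_encode",
    "coo_decode",
    "csc_encode",
    "csc_decode",
    "csr_encode",
    "csr_decode",
    "csr_from_triplets",
    "csc_to_triplets",
    "csr_to_triplets",
]


def _labels_or_default(m, n, row_labels, col_labels):
    return (
        row_labels if row_labels is not None else default_row_labels(m),
        col_labels if col_labels is not None else default_col_labels(n),
    )


@dataclass
class TripletSet:
    """COO storage: parallel (row, column, value) arrays, 0-based."""

    I: np.ndarray
    J: np.ndarray
    V: np.ndarray
    m: int
    n: int

    @property
    def nnz(self) -> int:
        return len(self.V)

    def validate(self) -> None:
        I, J, V = np.asarray(self.I), np.asarray(self.J), np.asarray(self.V)
        if not (len(I) == len(J) == len(V)):
            raise IntegrityError("triplet arrays have unequal lengths")
        if len(I) and (I.min() < 0 or I.max() >= self.m or J.min() < 0 or J.max() >= self.n):
            raise IntegrityError("triplet index out of bounds")
        if len(I):
            flat = I.astype(np.int64) * self.n + J.astype(np.int64)
            if len(np.unique(flat)) != len(flat):
                raise IntegrityError("duplicate (row, column) coordinate in triplets")
        if np.any(V == 0):
            raise IntegrityError("explicit zero value in triplets")


def _validate_compressed(indptr, indices, values, n_ptr_axis, n_idx_axis, axis_word):
    indptr = np.asarray(indptr)
    if len(indptr) != n_ptr_axis + 1 or indptr[0] != 0:
        raise IntegrityError(f"indptr must have length {n_ptr_axis + 1} and start at 0")
    if np.any(np.diff(indptr) < 0):
        raise IntegrityError("indptr is not non-decreasing")
    if indptr[-1] != len(indices) or len(indices) != len(values):
        raise IntegrityError("indptr[-1] does not match stored array lengths")
    if len(indices):
        if indices.min() < 0 or indices.max() >= n_idx_axis:
            raise IntegrityError(f"{axis_word} index out of bounds")
        if len(indices) > 1:
            d = np.diff(indices)
            within = np.ones(len(d), dtype=bool)
            # positions crossing a pointer boundary are exempt from ordering
            starts = indptr[1:-1] - 1
            starts = starts[(starts >= 0) & (starts < len(d))]
            within[starts] = False
            if np.any(d[within] <= 0):
                raise IntegrityError(
                    f"{axis_word} indices not strictly increasing within a segment"
                )
    if np.any(np.asarray(values) == 0):
        raise IntegrityError("explicit zero value in compressed form")


@dataclass
class CSCForm:
    """Compressed sparse column: one pointer per column into shared arrays."""

    indptr: np.ndarray
    indices: np.ndarray  # row indices, sorted within each column
    values: np.ndarray
    m: int
    n: int

    @property
    def nnz(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        _validate_compressed(self.indptr, np.asarray(self.indices), self.values, self.n, self.m, "row")


@dataclass
class CSRForm:
    """Compressed sparse row: the CSC layout with rows and columns exchanged."""

    indptr: np.ndarray
    indices: np.ndarray  # column indices, sorted within each row
    values: np.ndarray
    m: int
    n: int

    @property
    def nnz(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        _validate_compressed(self.indptr, np.asarray(self.indices), self.values, self.m, self.n, "column")


def coo_encode(M: MutationMatrix) -> TripletSet:
    """Row-major scan of the dense matrix into canonical (row, col, value) triplets."""
    A = M.values
    I, J = np.nonzero(A)
    return TripletSet(I=I.astype(np.int64), J=J.astype(np.int64), V=A[I, J].copy(), m=M.m, n=M.n)


def coo_decode(T: TripletSet, row_labels=None, col_labels=None) -> MutationMatrix:
    """Rebuild the dense matrix one triplet at a time."""
    T.validate()
    A = np.zeros((T.m, T.n), dtype=np.asarray(T.V).dtype)
    for r, c, v in zip(T.I, T.J, T.V):
        A[r, c] = v
    rl, cl = _labels_or_default(T.m, T.n, row_labels, col_labels)
    return MutationMatrix(rl, cl, A)


def csc_encode(M: MutationMatrix) -> CSCForm:
    """Column-precedence traversal: gather each column's non-zero rows in turn."""
    A = M.values
    m, n = A.shape
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_chunks = []
    val_chunks = []
    for j in range(n):
        col = A[:, j]
        rows = np.flatnonzero(col)
        idx_chunks.append(rows)
        val_chunks.append(col[rows])
        indptr[j + 1] = indptr[j] + rows.size
    indices = np.concatenate(idx_chunks) if idx_chunks else np.empty(0, dtype=np.int64)
    values = np.concatenate(val_chunks) if val_chunks else np.empty(0, dtype=A.dtype)
    return CSCForm(indptr=indptr, indices=indices.astype(np.int64), values=values, m=m, n=n)


def csc_decode(C: CSCForm, row_labels=None, col_labels=None) -> MutationMatrix:
    """Rebuild the dense matrix one pointer-delimited column slice at a time."""
    C.validate()
    A = np.zeros((C.m, C.n), dtype=np.asarray(C.values).dtype)
    indptr, indices, values = C.indptr, C.indices, C.values
    for j in range(C.n):
        s, e = indptr[j], indptr[j + 1]
        A[indices[s:e], j] = values[s:e]
    rl, cl = _labels_or_default(C.m, C.n, row_labels, col_labels)
    return MutationMatrix(rl, cl, A)


def csr_encode(M: MutationMatrix) -> CSRForm:
    """Row-precedence traversal: gather each row's non-zero columns in turn."""
    A = M.values
    m, n = A.shape
    indptr = np.zeros(m + 1, dtype=np.int64)
    idx_chunks = []
    val_chunks = []
    for i in range(m):
        row = A[i, :]
        cols = np.flatnonzero(row)
        idx_chunks.append(cols)
        val_chunks.append(row[cols])
        indptr[i + 1] = indptr[i] + cols.size
    indices = np.concatenate(idx_chunks) if idx_chunks else np.empty(0, dtype=np.int64)
    values = np.concatenate(val_chunks) if val_chunks else np.empty(0, dtype=A.dtype)
    return CSRForm(indptr=indptr, indices=indices.astype(np.int64), values=values, m=m, n=n)


def csr_decode(C: CSRForm, row_labels=None, col_labels=None) -> MutationMatrix:
    """Rebuild the dense matrix one pointer-delimited row slice at a time."""
    C.validate()
    A = np.zeros((C.m, C.n), dtype=np.asarray(C.values).dtype)
    indptr, indices, values = C.indptr, C.indices, C.values
    for i in range(C.m):
        s, e = indptr[i], indptr[i + 1]
        A[i, indices[s:e]] = values[s:e]
    rl, cl = _labels_or_default(C.m, C.n, row_labels, col_labels)
    return MutationMatrix(rl, cl, A)


def csr_from_triplets(I, J, V, m: int, n: int) -> CSRForm:
    """Assemble CSR directly from (unsorted, duplicate-free) triplets."""
    I = np.asarray(I, dtype=np.int64)
    J = np.asarray(J, dtype=np.int64)
    V = np.asarray(V)
    order = np.argsort(I * n + J, kind="stable")  # single composite key
    I, J, V = I[order], J[order], V[order]
    counts = np.bincount(I, minlength=m)
    indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return CSRForm(indptr=indptr, indices=J, values=V, m=m, n=n)


def csc_to_triplets(C: CSCForm) -> TripletSet:
    """Column-major (column, row, value) stream of a CSC form, as triplets."""
    cols = np.repeat(np.arange(C.n, dtype=np.int64), np.diff(C.indptr))
    return TripletSet(I=np.asarray(C.indices, dtype=np.int64), J=cols, V=np.asarray(C.values), m=C.m, n=C.n)


def csr_to_triplets(C: CSRForm) -> TripletSet:
    """Row-major (row, column, value) stream of a CSR form, as triplets."""
    rows = np.repeat(np.arange(C.m, dtype=np.int64), np.diff(C.indptr))
    return TripletSet(I=rows, J=np.asarray(C.indices, dtype=np.int64), V=np.asarray(C.values), m=C.m, n=C.n)
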