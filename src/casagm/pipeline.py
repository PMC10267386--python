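"""Lossless compression pipelines and the `.casg` container format.

Three codecs share one container:

* ``coo``    — canonical row-major triplets, stored directly.
* ``csc``    — compressed sparse column, stored directly.
* ``casagm`` — the optimized pipeline: the non-zeros are presorted in
  row-major order, the rows and columns are renumbered by reverse
  Cuthill-McKee (bandwidth reduction pulls scattered non-zeros toward the
  diagonal), and the renumbered matrix is CSR-encoded.  Both renumbering
  permutations are stored in the container, which is what makes the
  pipeline lossless: decompression decodes the CSR payload and inverts
  the stored permutations, recovering the original cell order exactly.

Container layout (little-endian, byte-deterministic; extension ``.casg``):

    offset  field
    0       magic ``b"CASG"``
    4       version  (u8, currently 1)
    5       codec    (u8: 0=coo, 1=csc, 2=casagm)
    6       flags    (u8: bit0 = labels stored, bit1 = permutations stored)
    7       value dtype code (u8: 1=int8, 2=int16, 4=int32, 8=int64, 16=float64)
    8       index dtype code (u8: 2=uint16, 4=uint32, 8=uint64)
    9..11   zero padding
    12      m   (u64)    20  n (u64)    28  nnz (u64)
    36      index arrays: coo -> I[nnz], J[nnz]; csc -> indptr[n+1], indices[nnz];
            casagm -> indptr[m+1], indices[nnz]
    ...     values[nnz] (value dtype)
    ...     casagm only: row_perm[m], col_perm[n] (index dtype)
    ...     labels, if flagged: u32 byte length + UTF-8 blob of the
            newline-joined row labels, then the same for column labels

The index width is the smallest of {16, 32, 64} bits that holds
max(m, n, nnz); the value dtype is the smallest signed integer width that
holds the data, or float64 for real-valued matrices.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import codecs
from .codecs import CSCForm, CSRForm, TripletSet
from .errors import FormatError, IntegrityError
from .matrixio import MutationMatrix, default_col_labels, default_row_labels
from .rcm import PermutationPair, rcm_permutations, row_major_presort

__all__ = [
    "CODEC_COO",
    "CODEC_CSC",
    "CODEC_CASAGM",
    "CODECS",
    "CompressedContainer",
    "compress",
    "decompress",
    "serialize",
    "serialize_bytes",
    "deserialize",
    "deserialize_bytes",
]

CODEC_COO = "coo"
CODEC_CSC = "csc"
CODEC_CASAGM = "casagm"
CODECS = (CODEC_COO, CODEC_CSC, CODEC_CASAGM)

MAGIC = b"CASG"
VERSION = 1
_CODEC_CODES = {CODEC_COO: 0, CODEC_CSC: 1, CODEC_CASAGM: 2}
_CODEC_NAMES = {v: k for k, v in _CODEC_CODES.items()}
_VALUE_DTYPES = {1: np.dtype("<i1"), 2: np.dtype("<i2"), 4: np.dtype("<i4"),
                 8: np.dtype("<i8"), 16: np.dtype("<f8")}
_INDEX_DTYPES = {2: np.dtype("<u2"), 4: np.dtype("<u4"), 8: np.dtype("<u8")}
_HEADER = struct.Struct("<4sBBBBB3xQQQ")  # 36 bytes


@dataclass
class CompressedContainer:
    """One encoded matrix plus everything needed to invert it exactly."""

    codec: str
    m: int
    n: int
    nnz: int
    value_dtype: np.dtype
    index_dtype: np.dtype
    values: np.ndarray
    # coo payload
    I: np.ndarray | None = None
    J: np.ndarray | None = None
    # csc / casagm payload
    indptr: np.ndarray | None = None
    indices: np.ndarray | None = None
    # casagm only
    row_perm: np.ndarray | None = None
    col_perm: np.ndarray | None = None
    # optional label block
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def array_bytes(self) -> int:
        """In-memory payload size: index + value + permutation arrays only."""
        total = self.values.nbytes
        for a in (self.I, self.J, self.indptr, self.indices, self.row_perm, self.col_perm):
            if a is not None:
                total += a.nbytes
        return total


def _pick_value_dtype(A: np.ndarray) -> np.dtype:
    if A.dtype.kind in "iu":
        lo = int(A.min()) if A.size else 0
        hi = int(A.max()) if A.size else 0
        for code in (1, 2, 4, 8):
            dt = _VALUE_DTYPES[code]
            info = np.iinfo(dt)
            if info.min <= lo and hi <= info.max:
                return dt
    return _VALUE_DTYPES[16]


def _pick_index_dtype(m: int, n: int, nnz: int) -> np.dtype:
    top = max(m, n, nnz)
    for code in (2, 4, 8):
        if top <= np.iinfo(_INDEX_DTYPES[code]).max:
            return _INDEX_DTYPES[code]
    raise ValueError("matrix too large to index")  # pragma: no cover


def compress(M: MutationMatrix, codec: str, include_labels: bool = True) -> CompressedContainer:
    """Encode a matrix under one of the three codecs.

    The ``casagm`` path runs row-major presort -> RCM renumbering -> CSR
    encoding and keeps the permutations; ``coo``/``csc`` encode directly.
    """
    if codec not in CODECS:
        raise ValueError(f"unknown codec {codec!r}; expected one of {CODECS}")
    m, n = M.shape
    vdt = _pick_value_dtype(M.values)
    base = dict(
        codec=codec, m=m, n=n,
        row_labels=list(M.row_labels) if include_labels else None,
        col_labels=list(M.col_labels) if include_labels else None,
    )
    if codec == CODEC_COO:
        T = codecs.coo_encode(M)
        idt = _pick_index_dtype(m, n, T.nnz)
        return CompressedContainer(
            nnz=T.nnz, value_dtype=vdt, index_dtype=idt,
            I=T.I.astype(idt), J=T.J.astype(idt), values=T.V.astype(vdt), **base,
        )
    if codec == CODEC_CSC:
        C = codecs.csc_encode(M)
        idt = _pick_index_dtype(m, n, C.nnz)
        return CompressedContainer(
            nnz=C.nnz, value_dtype=vdt, index_dtype=idt,
            indptr=C.indptr.astype(idt), indices=C.indices.astype(idt),
            values=C.values.astype(vdt), **base,
        )
    # casagm: presort, renumber, CSR-encode in the new numbering
    T = row_major_presort(codecs.coo_encode(M))
    if T.nnz == 0:
        P = PermutationPair.identity(m, n)  # nothing to reorder
    else:
        P = rcm_permutations(T)  # graph built from the already-extracted pattern
    csr = codecs.csr_from_triplets(P.row_perm[T.I], P.col_perm[T.J], T.V, m, n)
    idt = _pick_index_dtype(m, n, csr.nnz)
    return CompressedContainer(
        nnz=csr.nnz, value_dtype=vdt, index_dtype=idt,
        indptr=csr.indptr.astype(idt), indices=csr.indices.astype(idt),
        values=csr.values.astype(vdt),
        row_perm=P.row_perm.astype(idt), col_perm=P.col_perm.astype(idt), **base,
    )


def _container_labels(C: CompressedContainer):
    rl = C.row_labels if C.row_labels is not None else default_row_labels(C.m)
    cl = C.col_labels if C.col_labels is not None else default_col_labels(C.n)
    return rl, cl


def decompress(C: CompressedContainer) -> MutationMatrix:
    """Exact inverse of :func:`compress`, original row/column order included."""
    rl, cl = _container_labels(C)
    m, n = C.m, C.n
    if C.codec == CODEC_COO:
        T = TripletSet(I=C.I.astype(np.int64), J=C.J.astype(np.int64), V=C.values, m=m, n=n)
        return codecs.coo_decode(T, rl, cl)
    if C.codec == CODEC_CSC:
        form = CSCForm(indptr=C.indptr.astype(np.int64), indices=C.indices.astype(np.int64),
                       values=C.values, m=m, n=n)
        return codecs.csc_decode(form, rl, cl)
    if C.codec == CODEC_CASAGM:
        if C.row_perm is None or C.col_perm is None:
            raise IntegrityError("casagm container is missing its permutations")
        form = CSRForm(indptr=C.indptr.astype(np.int64), indices=C.indices.astype(np.int64),
                       values=C.values, m=m, n=n)
        form.validate()
        P = PermutationPair(C.row_perm.astype(np.int64), C.col_perm.astype(np.int64))
        old_col = np.empty(n, dtype=np.int64)
        old_col[C.col_perm.astype(np.int64)] = np.arange(n)
        A = np.zeros((m, n), dtype=C.values.dtype)
        indptr, indices, values = form.indptr, form.indices, form.values
        # walk rows in original order, reading each one's permuted CSR slice
        for i in range(m):
            p = P.row_perm[i]
            s, e = indptr[p], indptr[p + 1]
            A[i, old_col[indices[s:e]]] = values[s:e]
        return MutationMatrix(rl, cl, A)
    raise IntegrityError(f"container has unknown codec {C.codec!r}")


def _label_blob(labels: list[str]) -> bytes:
    return "\n".join(labels).encode("utf-8")


def serialize_bytes(C: CompressedContainer) -> bytes:
    """Byte-deterministic serialization (no timestamps, fixed field order)."""
    flags = 0
    if C.row_labels is not None:
        flags |= 1
    if C.row_perm is not None:
        flags |= 2
    vcode = {1: 1, 2: 2, 4: 4, 8: 8}.get(C.value_dtype.itemsize if C.value_dtype.kind == "i" else 0, 16)
    icode = C.index_dtype.itemsize
    parts = [_HEADER.pack(MAGIC, VERSION, _CODEC_CODES[C.codec], flags, vcode, icode,
                          C.m, C.n, C.nnz)]
    if C.codec == CODEC_COO:
        arrays = [C.I, C.J]
    else:
        arrays = [C.indptr, C.indices]
    for a in arrays:
        parts.append(np.ascontiguousarray(a, dtype=C.index_dtype).tobytes())
    parts.append(np.ascontiguousarray(C.values, dtype=C.value_dtype).tobytes())
    if C.row_perm is not None:
        parts.append(np.ascontiguousarray(C.row_perm, dtype=C.index_dtype).tobytes())
        parts.append(np.ascontiguousarray(C.col_perm, dtype=C.index_dtype).tobytes())
    if C.row_labels is not None:
        rb = _label_blob(C.row_labels)
        cb = _label_blob(C.col_labels)
        parts.append(struct.pack("<I", len(rb)))
        parts.append(rb)
        parts.append(struct.pack("<I", len(cb)))
        parts.append(cb)
    return b"".join(parts)


def serialize(C: CompressedContainer, path: str | Path) -> int:
    """Write the container to `path`; returns the byte count written."""
    blob = serialize_bytes(C)
    with open(path, "wb") as fh:
        fh.write(blob)
    return len(blob)


class _Reader:
    def __init__(self, blob: bytes):
        self.blob = blob
        self.off = 0

    def take(self, nbytes: int, what: str) -> bytes:
        if self.off + nbytes > len(self.blob):
            raise IntegrityError(
                f"truncated container: needed {nbytes} bytes for {what} "
                f"at offset {self.off}, only {len(self.blob) - self.off} left"
            )
        out = self.blob[self.off : self.off + nbytes]
        self.off += nbytes
        return out

    def array(self, count: int, dtype: np.dtype, what: str) -> np.ndarray:
        raw = self.take(count * dtype.itemsize, what)
        return np.frombuffer(raw, dtype=dtype).copy()


def deserialize_bytes(blob: bytes) -> CompressedContainer:
    rd = _Reader(blob)
    magic, version, ccode, flags, vcode, icode, m, n, nnz = _HEADER.unpack(rd.take(_HEADER.size, "header"))
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}; not a .casg container")
    if version != VERSION:
        raise FormatError(f"unsupported container version {version}")
    if ccode not in _CODEC_NAMES:
        raise IntegrityError(f"unknown codec code {ccode}")
    if vcode not in _VALUE_DTYPES or icode not in _INDEX_DTYPES:
        raise IntegrityError(f"unknown dtype codes value={vcode} index={icode}")
    codec = _CODEC_NAMES[ccode]
    vdt, idt = _VALUE_DTYPES[vcode], _INDEX_DTYPES[icode]
    kw: dict = {}
    if codec == CODEC_COO:
        kw["I"] = rd.array(nnz, idt, "I")
        kw["J"] = rd.array(nnz, idt, "J")
    elif codec == CODEC_CSC:
        kw["indptr"] = rd.array(n + 1, idt, "indptr")
        kw["indices"] = rd.array(nnz, idt, "indices")
    else:
        kw["indptr"] = rd.array(m + 1, idt, "indptr")
        kw["indices"] = rd.array(nnz, idt, "indices")
    values = rd.array(nnz, vdt, "values")
    if flags & 2:
        kw["row_perm"] = rd.array(m, idt, "row_perm")
        kw["col_perm"] = rd.array(n, idt, "col_perm")
    elif codec == CODEC_CASAGM:
        raise IntegrityError("casagm container is missing its permutations")
    row_labels = col_labels = None
    if flags & 1:
        (rlen,) = struct.unpack("<I", rd.take(4, "row label length"))
        row_labels = rd.take(rlen, "row labels").decode("utf-8").split("\n")
        (clen,) = struct.unpack("<I", rd.take(4, "column label length"))
        col_labels = rd.take(clen, "column labels").decode("utf-8").split("\n")
        if len(row_labels) != m or len(col_labels) != n:
            raise IntegrityError("label counts do not match declared dimensions")
    if rd.off != len(blob):
        raise IntegrityError(f"{len(blob) - rd.off} trailing bytes after offset {rd.off}")
    C = CompressedContainer(
        codec=codec, m=m, n=n, nnz=nnz, value_dtype=vdt, index_dtype=idt,
        values=values, row_labels=row_labels, col_labels=col_labels, **kw,
    )
    _check_integrity(C)
    return C


def _check_integrity(C: CompressedContainer) -> None:
    if C.codec == CODEC_COO:
        if len(C.I) != C.nnz or len(C.J) != C.nnz or len(C.values) != C.nnz:
            raise IntegrityError("declared nnz does not match stored array lengths")
    else:
        if len(C.indices) != C.nnz or len(C.values) != C.nnz:
            raise IntegrityError("declared nnz does not match stored array lengths")
        if int(C.indptr[-1]) != C.nnz:
            raise IntegrityError("indptr[-1] does not match declared nnz")
    if C.row_perm is not None:
        for name, p, k in (("row_perm", C.row_perm, C.m), ("col_perm", C.col_perm, C.n)):
            if not np.array_equal(np.sort(p.astype(np.int64)), np.arange(k)):
                raise IntegrityError(f"stored {name} is not a valid permutation")


def deserialize(path: str | Path) -> CompressedContainer:
    with open(path, "rb") as fh:
        return deserialize_bytes(fh.read())
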