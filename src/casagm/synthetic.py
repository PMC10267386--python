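"""Seeded generators for mutation-like matrices.

Real SNV tables are sample-by-gene counts of somatic single-nucleotide
calls: very sparse (well under 2% non-zero), small non-negative integers.
CNV tables tabulate copy-number gain/loss calls: much denser (roughly
3-50% non-zero) and signed, with a characteristic share of positive
entries.  The generators here reproduce those storage-relevant traits —
dimensions, an exactly controlled non-zero count, value sign structure,
and optional banded or clustered placement — without attempting any
biological realism (no mutation signatures, hotspots or correlations).

``paper_regime_suite`` instantiates the two published benchmark panels:
nine SNV-like matrices and six CNV-like matrices whose (rows, size,
non-zero count, sign share) match the published characterization tables;
column counts are derived as size/rows, which is integral for every
panel row.  All randomness flows through ``numpy.random.default_rng``
seeded from the caller's seed, so identical specs yield identical
matrices across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .matrixio import MutationMatrix, default_col_labels, default_row_labels
from .rcm import PermutationPair, apply_permutations

__all__ = [
    "GeneratorSpec",
    "generate",
    "shuffle_axes",
    "paper_regime_suite",
    "SNV_PANEL",
    "CNV_PANEL",
]

# Published SNV panel characteristics:
# (name, dataset size m*n, non-zero count, printed sparsity %, rows,
#  printed rows/columns %)
SNV_PANEL = (
    ("brain_tumor", 1006707, 395, 0.039, 83, 0.684),
    ("acute_myelogenous_leukemia", 2377284, 1683, 0.071, 196, 1.616),
    ("thyroid_carcinoma", 4863729, 4780, 0.098, 401, 3.306),
    ("prostate_cancer", 4038957, 9004, 0.223, 333, 2.745),
    ("ovarian_cancer", 3832764, 12873, 0.336, 316, 2.605),
    ("breast_cancer", 6202131, 20287, 0.327, 507, 4.145),
    ("bladder_cancer", 1576770, 25368, 1.609, 130, 1.072),
    ("kidney_clear_cell_carcinoma", 5142696, 24023, 0.470, 424, 3.496),
    ("colorectal_cancer", 2716896, 48038, 1.768, 224, 1.847),
)

# Published CNV panel characteristics:
# (name, dataset size, non-zero count, printed non-negative ratio %,
#  printed sparsity %, rows, printed rows/columns %)
CNV_PANEL = (
    ("acute_myelogenous_leukemia", 2316639, 81104, 48.12, 3.50, 191, 1.574738),
    ("thyroid_carcinoma", 6015984, 189060, 58.81, 3.14, 496, 4.089373),
    ("prostate_cancer", 4038957, 556304, 38.74, 13.77, 333, 2.745486),
    ("colorectal_cancer", 3117153, 753833, 54.11, 24.18, 257, 2.118889),
    ("bladder_cancer", 1552512, 780530, 53.59, 50.28, 128, 1.055322),
    ("kidney_clear_cell_carcinoma", 5288244, 1196243, 50.32, 22.62, 436, 3.59469),
)

_VALUE_MODELS = ("snv_counts", "cnv_signed")
_STRUCTURES = ("uniform", "banded", "clustered")


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic matrix.

    Exactly one of ``sparsity_pct`` / ``nnz`` fixes the non-zero count
    (``nnz`` wins when both are given; ``sparsity_pct`` is rounded to a
    count).  ``nonneg_ratio_pct`` applies to the ``cnv_signed`` model
    only and fixes the exact number of positive entries.
    """

    m: int
    n: int
    sparsity_pct: float | None = None
    nnz: int | None = None
    value_model: str = "snv_counts"
    nonneg_ratio_pct: float = 50.0
    structure: str = "uniform"
    band_width: int | None = None
    clusters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise SpecError("dimensions must be positive")
        if self.nnz is None:
            if self.sparsity_pct is None:
                raise SpecError("one of sparsity_pct or nnz is required")
            if not 0.0 < self.sparsity_pct <= 100.0:
                raise SpecError("sparsity_pct must lie in (0, 100]")
            self.nnz = int(np.floor(self.sparsity_pct * self.m * self.n / 100.0 + 0.5))
        if not 0 <= self.nnz <= self.m * self.n:
            raise SpecError(f"nnz={self.nnz} exceeds matrix size {self.m * self.n}")
        if self.value_model not in _VALUE_MODELS:
            raise SpecError(f"value_model must be one of {_VALUE_MODELS}")
        if not 0.0 <= self.nonneg_ratio_pct <= 100.0:
            raise SpecError("nonneg_ratio_pct must lie in [0, 100]")
        if self.structure not in _STRUCTURES:
            raise SpecError(f"structure must be one of {_STRUCTURES}")
        if self.structure == "banded":
            if self.band_width is None or not 0 <= self.band_width < max(self.m, self.n):
                raise SpecError("banded structure needs 0 <= band_width < max(m, n)")
        if self.structure == "clustered" and (self.clusters is None or self.clusters < 1):
            raise SpecError("clustered structure needs clusters >= 1")


def _banded_cells(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample cells uniformly among those with |i - j*m/n| <= band_width."""
    m, n, bw = spec.m, spec.n, spec.band_width
    i = np.arange(m)
    lo = np.ceil((i - bw) * n / m).astype(np.int64).clip(0, n - 1)
    hi = np.floor((i + bw) * n / m).astype(np.int64).clip(0, n - 1)
    counts = np.maximum(hi - lo + 1, 0)
    total = int(counts.sum())
    if spec.nnz > total:
        raise SpecError(f"band holds only {total} cells, {spec.nnz} requested")
    picks = np.sort(rng.choice(total, size=spec.nnz, replace=False))
    ends = np.cumsum(counts)
    row = np.searchsorted(ends, picks, side="right")
    offset = picks - (ends[row] - counts[row])
    col = lo[row] + offset
    return row * np.int64(n) + col


def _clustered_cells(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact-count sampling around cluster centers, topped up uniformly."""
    m, n, k = spec.m, spec.n, spec.clusters
    centers_r = rng.integers(0, m, size=k)
    centers_c = rng.integers(0, n, size=k)
    sig_r = max(1.0, m / (4.0 * k))
    sig_c = max(1.0, n / (4.0 * k))
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    for _ in range(64):
        need = spec.nnz - len(chosen)
        if need <= 0:
            break
        which = rng.integers(0, k, size=2 * need + 16)
        r = np.clip(np.round(centers_r[which] + rng.normal(0, sig_r, size=len(which))), 0, m - 1)
        c = np.clip(np.round(centers_c[which] + rng.normal(0, sig_c, size=len(which))), 0, n - 1)
        cand = (r.astype(np.int64) * n + c.astype(np.int64))
        chosen = np.unique(np.concatenate([chosen, cand]))
        if len(chosen) > spec.nnz:
            chosen = rng.choice(chosen, size=spec.nnz, replace=False)
    if len(chosen) < spec.nnz:  # dense clusters saturated; fill uniformly
        taken = np.zeros(m * n, dtype=bool)
        taken[chosen] = True
        rest = np.flatnonzero(~taken)
        extra = rng.choice(rest, size=spec.nnz - len(chosen), replace=False)
        chosen = np.concatenate([chosen, extra])
    return chosen


def _values(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.value_model == "snv_counts":
        return rng.integers(1, 10, size=spec.nnz, dtype=np.int64).astype(np.int8)
    n_pos = int(np.floor(spec.nonneg_ratio_pct * spec.nnz / 100.0 + 0.5))
    mags = rng.integers(1, 5, size=spec.nnz, dtype=np.int64).astype(np.int8)
    signs = np.ones(spec.nnz, dtype=np.int8)
    signs[n_pos:] = -1
    rng.shuffle(signs)
    # the shuffle preserves the exact positive count
    return mags * signs


def generate(spec: GeneratorSpec) -> MutationMatrix:
    """Materialize one seeded matrix with the exact requested non-zero count."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    if spec.structure == "uniform":
        cells = rng.choice(m * n, size=spec.nnz, replace=False)
    elif spec.structure == "banded":
        cells = _banded_cells(spec, rng)
    else:
        cells = _clustered_cells(spec, rng)
    cells = np.sort(cells)
    A = np.zeros(m * n, dtype=np.int8)
    A[cells] = _values(spec, rng)
    A = A.reshape(m, n)
    return MutationMatrix(default_row_labels(m), default_col_labels(n), A)


def shuffle_axes(M: MutationMatrix, seed: int, symmetric: bool = False):
    """Randomly renumber rows and columns; returns the permutations used.

    ``symmetric=True`` applies one shared permutation to both axes of a
    square matrix, preserving pattern symmetry (the setting under which
    RCM provably recovers banded structure).
    """
    rng = np.random.default_rng(seed)
    row_order = rng.permutation(M.m)
    if symmetric:
        if M.m != M.n:
            raise SpecError("symmetric shuffle requires a square matrix")
        col_order = row_order
    else:
        col_order = rng.permutation(M.n)
    P = PermutationPair(np.argsort(row_order), np.argsort(col_order))
    return apply_permutations(M, P), P


def paper_regime_suite(kind: str, seed: int = 0) -> list[tuple[str, MutationMatrix]]:
    """The published benchmark panels as named synthetic matrices.

    ``kind="snv"`` yields the nine SNV-like matrices, ``kind="cnv"`` the
    six CNV-like ones (with their published non-negative ratios).
    """
    if kind not in ("snv", "cnv"):
        raise SpecError("kind must be 'snv' or 'cnv'")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=16)
    out = []
    if kind == "snv":
        for k, (name, size, nnz, _sp, rows, _rc) in enumerate(SNV_PANEL):
            cols, rem = divmod(size, rows)
            assert rem == 0
            spec = GeneratorSpec(m=rows, n=cols, nnz=nnz, value_model="snv_counts",
                                 seed=int(child_seeds[k]))
            out.append((name, generate(spec)))
    else:
        for k, (name, size, nnz, nonneg, _sp, rows, _rc) in enumerate(CNV_PANEL):
            cols, rem = divmod(size, rows)
            assert rem == 0
            spec = GeneratorSpec(m=rows, n=cols, nnz=nnz, value_model="cnv_signed",
                                 nonneg_ratio_pct=nonneg, seed=int(child_seeds[k]))
            out.append((name, generate(spec)))
    return out
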