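"""Reverse Cuthill-McKee reordering for sparse mutation matrices.

Scattered non-zero cells give a mutation matrix a large bandwidth — the
widest |i - j| distance of a non-zero from the diagonal.  Cuthill-McKee
renumbers the nodes of the matrix's undirected graph by a breadth-first
traversal that starts at a minimum-degree node and visits neighbors in
increasing degree order, which tends to pull connected structure toward
the diagonal; reversing the resulting order (reverse Cuthill-McKee, RCM)
is the classic refinement that usually does at least as well.

Mutation matrices are rectangular (samples x genes) and structurally
asymmetric, so two graph constructions are provided:

* ``square`` — nodes are the rows of a square matrix, with an edge (i, j)
  whenever A[i, j] or A[j, i] is non-zero (pattern symmetrized, diagonal
  dropped).  One ordering renumbers rows and columns identically.
* ``bipartite`` — nodes are the m rows followed by the n columns, with an
  edge (i, m + j) whenever A[i, j] is non-zero.  The RCM order of this
  graph, split into its row-node and column-node subsequences, yields
  independent row and column renumberings; this is the standard
  generalization for rectangular matrices.

Algorithm details, fixed for determinism: the traversal starts at the
globally minimum-degree unvisited node (ties broken by lowest index), the
degree of a node counts its off-diagonal neighbors only, neighbors are
appended to the queue in increasing (degree, index) order, and each
exhausted component is followed by a restart at the next minimum-degree
unvisited node, so disconnected graphs (common at SNV sparsity, where most
genes carry no call) are handled.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .codecs import TripletSet
from .matrixio import MutationMatrix

__all__ = [
    "AdjacencyGraph",
    "PermutationPair",
    "build_adjacency",
    "node_degrees",
    "cuthill_mckee",
    "reverse_ordering",
    "rcm_ordering",
    "rcm_permutations",
    "apply_permutations",
    "invert_permutations",
    "bandwidth",
    "row_major_presort",
]


@dataclass
class AdjacencyGraph:
    """Undirected graph in CSR adjacency form (no self-loops).

    Neighbor lists are stored pre-sorted in increasing (degree, index)
    order — exactly the order the Cuthill-McKee traversal consumes them —
    so the traversal itself never sorts.  ``n_row_nodes`` tags node
    origins: in bipartite mode node ``i < n_row_nodes`` is matrix row
    ``i`` and node ``n_row_nodes + j`` is matrix column ``j``; in square
    mode every node is both row and column ``i``.
    """

    node_count: int
    indptr: np.ndarray
    indices: np.ndarray  # neighbor lists, ordered by (degree, index)
    n_row_nodes: int
    bipartite: bool

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]


@dataclass
class PermutationPair:
    """Row and column renumberings, stored as old-index -> new-index maps."""

    row_perm: np.ndarray
    col_perm: np.ndarray

    def __post_init__(self) -> None:
        for name, p in (("row_perm", self.row_perm), ("col_perm", self.col_perm)):
            p = np.asarray(p, dtype=np.int64)
            setattr(self, name, p)
            if not np.array_equal(np.sort(p), np.arange(len(p))):
                raise ValueError(f"{name} is not a permutation of 0..{len(p) - 1}")

    @classmethod
    def identity(cls, m: int, n: int) -> "PermutationPair":
        return cls(np.arange(m, dtype=np.int64), np.arange(n, dtype=np.int64))


def _as_pattern(X):
    """Accept a MutationMatrix, dense array, or precomputed triplets.

    Returns ``(m, n, I, J)`` with I/J the non-zero coordinates.
    """
    if isinstance(X, TripletSet):
        return X.m, X.n, np.asarray(X.I, dtype=np.int64), np.asarray(X.J, dtype=np.int64)
    A = X.values if isinstance(X, MutationMatrix) else np.asarray(X)
    I, J = np.nonzero(A)
    return A.shape[0], A.shape[1], I.astype(np.int64, copy=False), J.astype(np.int64, copy=False)


def _csr_from_edges(u: np.ndarray, v: np.ndarray, node_count: int):
    """CSR adjacency with each neighbor list ordered by (degree, index)."""
    deg = np.bincount(u, minlength=node_count)
    order = np.lexsort((v, deg[v], u))
    indptr = np.zeros(node_count + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    return indptr, v[order]


def build_adjacency(X, mode: str = "auto") -> AdjacencyGraph:
    """Turn a matrix pattern into the undirected graph RCM traverses.

    ``X`` may be a MutationMatrix, a dense array, or a TripletSet (so the
    pipeline can reuse coordinates it already extracted).  ``mode``:
    ``"auto"`` picks ``"square"`` for square input, else ``"bipartite"``;
    both can be forced explicitly.
    """
    m, n, I, J = _as_pattern(X)
    if mode == "auto":
        mode = "square" if m == n else "bipartite"
    if mode == "square":
        if m != n:
            raise ValueError("square mode requires a square matrix")
        u = np.concatenate([I, J])
        v = np.concatenate([J, I])
        keep = u != v  # self-loops (diagonal entries) excluded
        u, v = u[keep], v[keep]
        if len(u):
            flat = u * m + v
            uniq = np.unique(flat)
            u, v = uniq // m, uniq % m
        indptr, indices = _csr_from_edges(u, v, m)
        return AdjacencyGraph(m, indptr, indices, n_row_nodes=m, bipartite=False)
    if mode == "bipartite":
        u = np.concatenate([I, m + J])
        v = np.concatenate([m + J, I])
        indptr, indices = _csr_from_edges(u, v, m + n)
        return AdjacencyGraph(m + n, indptr, indices, n_row_nodes=m, bipartite=True)
    raise ValueError(f"unknown adjacency mode {mode!r}")


def node_degrees(G: AdjacencyGraph) -> np.ndarray:
    """Number of neighbors of each node (self-loops never counted)."""
    return np.diff(G.indptr)


def cuthill_mckee(G: AdjacencyGraph) -> np.ndarray:
    """The forward Cuthill-McKee visiting order.

    BFS from the minimum-degree unvisited node, appending unvisited
    neighbors in increasing (degree, index) order; restarts cover
    disconnected components.  Returns the node ordering R (position k
    holds the k-th visited node).
    """
    N = G.node_count
    deg = node_degrees(G)
    nbr = G.indices  # already in (degree, index) order per neighbor list
    indptr = G.indptr

    visited = np.zeros(N, dtype=bool)
    result = np.empty(N, dtype=np.int64)
    pos = 0
    starts = np.lexsort((np.arange(N), deg))  # min degree first, ties by index
    q: deque[int] = deque()
    for s in starts:
        if visited[s]:
            continue
        visited[s] = True
        q.append(int(s))
        while q:
            c = q.popleft()
            result[pos] = c
            pos += 1
            blk = nbr[indptr[c] : indptr[c + 1]]
            blk = blk[~visited[blk]]
            if blk.size:
                visited[blk] = True
                q.extend(blk.tolist())
    return result


def reverse_ordering(R: np.ndarray) -> np.ndarray:
    """Reverse a visiting order (the 'reverse' in reverse Cuthill-McKee)."""
    return np.asarray(R)[::-1].copy()


def rcm_ordering(G: AdjacencyGraph) -> np.ndarray:
    return reverse_ordering(cuthill_mckee(G))


def _ordering_to_perm(R: np.ndarray) -> np.ndarray:
    perm = np.empty(len(R), dtype=np.int64)
    perm[R] = np.arange(len(R))
    return perm


def rcm_permutations(X, mode: str = "auto") -> PermutationPair:
    """RCM row/column renumberings of a matrix (old index -> new index).

    Square inputs use the symmetrized-pattern graph (rows and columns share
    one ordering); rectangular inputs use the bipartite graph, whose RCM
    order is split into its row-node and column-node subsequences.
    ``X`` may also be a TripletSet holding the non-zero pattern.
    """
    G = build_adjacency(X, mode=mode)
    R = rcm_ordering(G)
    if not G.bipartite:
        perm = _ordering_to_perm(R)
        return PermutationPair(perm, perm.copy())
    m = G.n_row_nodes
    n = G.node_count - m
    row_nodes = R[R < m]
    col_nodes = R[R >= m] - m
    row_perm = np.empty(m, dtype=np.int64)
    row_perm[row_nodes] = np.arange(m)
    col_perm = np.empty(n, dtype=np.int64)
    col_perm[col_nodes] = np.arange(n)
    return PermutationPair(row_perm, col_perm)


def apply_permutations(M: MutationMatrix, P: PermutationPair) -> MutationMatrix:
    """Renumber: cell (i, j) moves to (row_perm[i], col_perm[j]); labels follow."""
    m, n = M.shape
    B = np.empty_like(M.values)
    B[P.row_perm[:, None], P.col_perm[None, :]] = M.values
    rl = [None] * m
    cl = [None] * n
    for i, lab in zip(P.row_perm, M.row_labels):
        rl[i] = lab
    for j, lab in zip(P.col_perm, M.col_labels):
        cl[j] = lab
    return MutationMatrix(rl, cl, B)


def invert_permutations(P: PermutationPair) -> PermutationPair:
    return PermutationPair(np.argsort(P.row_perm), np.argsort(P.col_perm))


def bandwidth(X) -> int:
    """Widest diagonal distance of a non-zero; 0 for an all-zero pattern.

    Square patterns use max |i - j|; rectangular patterns are measured on
    the (m+n)-node bipartite symmetric pattern, i.e. max |i - (m + j)|.
    """
    m, n, I, J = _as_pattern(X)
    if len(I) == 0:
        return 0
    if m == n:
        return int(np.max(np.abs(I - J)))
    return int(np.max(np.abs(I - (m + J))))


def row_major_presort(T: TripletSet) -> TripletSet:
    """Stable sort of triplets by (row, column) so neighbors sit adjacently.

    Idempotent; an already-sorted stream is detected in one linear pass
    and returned unchanged.
    """
    I = np.asarray(T.I, dtype=np.int64)
    J = np.asarray(T.J, dtype=np.int64)
    V = np.asarray(T.V)
    key = I * T.n + J
    if len(key) < 2 or np.all(key[1:] > key[:-1]):
        return TripletSet(I=I, J=J, V=V, m=T.m, n=T.n)
    order = np.argsort(key, kind="stable")
    return TripletSet(I=I[order], J=J[order], V=V[order], m=T.m, n=T.n)
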