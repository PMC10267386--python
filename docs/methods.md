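# Methods

## Data model

A mutation matrix is a labeled dense m×n numeric table, samples × genes.
SNV-style data are small non-negative integer counts; CNV-style data are
signed gain/loss values. Cells must be finite; labels are unique per axis.
Indices are 0-based half-open everywhere in memory; the MatrixMarket
boundary converts to/from the format's 1-based convention. Empty TSV
cells read as 0 (level-3 style tables are sparse by omission).

## Dataset characterization

`profile_dataset` reports: dataset size m·n, non-zero count, sparsity
100·nnz/(m·n) (note the convention: *higher sparsity = denser matrix*),
rows, 100·m/n, source file size, and three linear-algebra summaries whose
conventions we fix as the MATLAB defaults, since no single convention is
universal: the operator 1-norm (maximum absolute column sum), the
spectral norm (largest singular value), and the numerical rank counted
against the tolerance max(m,n)·eps·σ_max. Percentages are kept at full
precision internally and rounded half-up only at report time.

## Codecs

Canonical orders make every encoding unique and byte-stable: COO is
row-major (ties impossible), CSC/CSR keep indices strictly increasing
within each column/row. Explicit zeros are dropped at encode time;
duplicate coordinates are rejected as corrupt input rather than summed,
because a mutation table has exactly one cell per (sample, gene).

Implementation style is deliberately uniform and format-structural:
encoders traverse the dense matrix in the target format's canonical
order (one pass for COO, per-column gathers for CSC, per-row gathers for
CSR); decoders walk the compressed object's own access units — COO one
triplet at a time (the format exposes no block structure, which is
exactly its weakness), CSC/CSR one pointer-delimited slice at a time.
Decoders validate structural invariants before reconstructing.

## The CA_SAGM pipeline

1. **Row-major presort** of the triplet stream (idempotent; an already
   sorted stream is detected in one linear pass and passed through).
2. **Reverse Cuthill–McKee renumbering.** The matrix pattern becomes an
   undirected graph: for square matrices the symmetrized pattern on m
   nodes (edge i–j iff A[i,j] or A[j,i] ≠ 0, diagonal excluded); for
   rectangular matrices the bipartite graph on m+n nodes (edge i–(m+j)
   iff A[i,j] ≠ 0). The bipartite form is the standard generalization
   that yields independent row and column renumberings. The traversal is
   fixed for determinism: start at the globally minimum-degree unvisited
   node (ties → lowest index), append unvisited neighbors in increasing
   (degree, index) order, restart per component, reverse the final order.
   No pseudo-peripheral start search is used — deliberately the plain
   algorithm, not later refinements. An all-zero matrix skips the graph
   entirely and stores identity permutations.
3. **CSR encoding** of the renumbered triplets, assembled with a single
   composite-key sort.

Losslessness: nothing in CSR alone records the original numbering, so
the container stores both permutations (old → new); decompression reads
each original row's permuted CSR slice and maps column indices back
through the inverse column permutation. This is a design choice the
method description leaves open; without it the pipeline would be lossy.

## Container format

Little-endian, byte-deterministic, documented field-by-field in
`casagm/pipeline.py`. Index arrays use the smallest of {16, 32, 64}-bit
widths holding max(m, n, nnz); values use the smallest signed integer
width that fits, or float64 for real data. Labels are optional (a header
flag) so pure-numeric benchmarks measure the matrix alone. No entropy
coding: the codecs are structural, and stacking a byte-level compressor
on top is out of scope. Serialized size therefore obeys a closed form,
header (36 B) + index bytes + value bytes (+ permutations + labels),
which the tests verify per codec.

## Benchmark harness

CT and DCT are medians over `repetitions` runs (default 5; one extra
warm-up run is discarded) of `time.perf_counter_ns`. CR = uncompressed
bytes / CT, DCR likewise; MB = 10⁶ bytes; file-size "K" in CLI reports
is 2¹⁰ bytes. The uncompressed size is the dense in-memory footprint at
the value precision the container stores. CM is the serialized container
length (the in-memory array total is reported alongside, since either
reading is defensible). CRO = uncompressed bytes / CM. Before timing, a
full round trip is verified cell-for-cell; a mismatch aborts that cell
with an integrity error so a lossy run can never report timings.

Statistics: the paired t-test is t = mean(d)/(sd(d)/√k) with a two-sided
Student-t p on k−1 df; zero-variance differences are flagged as
degenerate rather than returned as NaN. Spearman's ρ is the Pearson
correlation of average-assigned (tie-aware) ranks with the
t-approximation p-value on k−2 df — the approximation is used even at
panel sizes of 6–9 to mirror how such tables are conventionally
reported. Both routines are checked against scipy to 1e-10 but are not
implemented by it. Pairwise p-values are reported raw (no multiplicity
correction), matching the study design being reproduced; summaries are
mean ± sample SD (n−1).

## Synthetic data

The generators reproduce the storage-relevant statistics of the
published TCGA panels, not their biology: exact non-zero counts (cells
sampled without replacement, so sparsity — the key covariate of the
correlation analyses — is controlled exactly), SNV values uniform on
{1..9}, CNV values as signed magnitudes on {1..4} with an exact positive
count set by the non-negative ratio. Value distributions are not
published; small integers were chosen to keep the norm columns
qualitatively in range. Placement is uniform by default; `banded`
restricts cells to |i − j·m/n| ≤ bw (the structure RCM provably
recovers after shuffling, used by the reordering tests) and `clustered`
draws around k Gaussian hotspots with uniform top-up to hit the exact
count. All randomness flows through `numpy.random.default_rng(seed)`
(PCG64), so identical specs give identical matrices across platforms;
ports to other RNGs will diverge and should say so.

`paper_regime_suite` instantiates the published panels exactly: nine
SNV-like matrices and six CNV-like matrices with the published rows,
sizes, non-zero counts and sign ratios; column counts are size/rows,
integral for all fifteen rows (n = 12129 throughout except one SNV panel
row with n = 12233). Passing benchmarks on these panels shows the codecs
behave correctly under realistic *sparsity geometry*; it says nothing
about real mutation data's value distributions, label structure or
hotspot correlation, which the generator does not model.

## Known limitations and non-reproducible claims

* Absolute wall-clock numbers from the original study (Windows/MATLAB)
  are hardware- and runtime-bound and are not reproduction targets; only
  orderings and trends are.
* Two published orderings are artifacts of the original implementation
  mix and do not hold when all three codecs are implemented at the same
  optimization level, as they are here: (1) at CNV-like density the
  CA_SAGM compression time cannot undercut CSC's single column-order
  pass, because the RCM stage must sort and traverse a graph with 2·nnz
  edge incidences (nnz ≫ n there); (2) at SNV-like scale COO
  decompression is not the slowest, because walking nnz ≈ 16k triplets
  is cheaper than walking n ≈ 12k column slices. Both orderings *do*
  hold in the regime where the structural argument applies (CA_SAGM
  compresses faster than CSC on the SNV panel; COO decompresses slowest
  on the CNV panel). The corresponding acceptance test asserts the full
  published orderings and is expected to fail on exactly those two
  sub-claims; the baseline codecs were not de-optimized to force them.
* RCM tie-breaking is deterministic but not unique across
  implementations; against the scipy reference the achieved bandwidths
  coincide on ~96% of random graphs and differ by ±1–3 otherwise, in
  both directions. Tests assert validity always and equality on the
  clear majority.
* The profile's norm/rank columns follow one fixed convention (above);
  published tables using a different convention will differ.
* Matrices are held dense in memory; the package targets benchmark-scale
  data (≤ ~10⁷ cells), not chromosome-scale streaming.

## Problem sizes used by the test suite

The acceptance tests run the full published panel dimensions (up to
507 × 12233) with 3 timing repetitions, a 200-matrix losslessness sweep
at 5–50 rows × 5–100 columns across 0.01–50% sparsity, shuffled
tridiagonal systems up to n = 200, and 100-graph oracle comparisons —
sizes chosen to exercise every regime while keeping the suite fast
enough to run routinely.
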