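# Methods

## Problem and model

Given N real vectors in d dimensions (columns of X) and a metric, the
package computes the exact k-nearest-neighbour graph: for every vector,
the k closest other vectors under a deterministic total order. No
approximation is involved anywhere; the design question is purely how
to organise O(N²d) work so that memory stays bounded and the result is
reproducible.

### Distance decomposition

Squared Euclidean distances are assembled from one Gram product per
block:

    D_qr = ν_q 𝟙ᵀ + 𝟙 ν_rᵀ − 2 X_qᵀ X_r

where ν is the vector of squared column norms, computed once per run as
a single array reduction and stored (never the rank-1 matrices
themselves). Cosine distance is `1 − G_ij / sqrt(ν_i ν_j)` from the same
Gram block G. Pearson distance is implemented *as* cosine distance of
the centred cloud — the same code path with a different tag — with
dataset-mean centring by default: μ is the per-dimension mean over all
N columns. A `per_vector` centring switch provides the textbook
correlation convention (each column centred by its own scalar mean) for
users who expect `1 − corrcoef`; the default remains the
centred-cosine convention because the whole pipeline then reuses one
centring of the input and the identity `pearson = cosine ∘ center`
holds exactly.

Selection for the Euclidean metric operates on squared distances
(monotone-equivalent, so neighbour ranks and tie behaviour are
unchanged); the square root is taken only when the graph is assembled,
so users see conventional units. Cosine/Pearson values are reported as
defined, clamped into [0, 2].

### Numerical choices

- 64-bit floats are the default and the basis of every stated
  tolerance. The Gram decomposition cancels catastrophically for
  near-duplicate points, so results are clamped: `max(0, ·)` for
  squared Euclidean, clip to [0, 2] for cosine. A 32-bit mode
  (`precision="32"`) exists for scale experiments and is excluded from
  exactness claims.
- Global self-pairs (block entries whose global row equals the global
  column) are pinned to exactly 0 rather than left at the ~1-ulp
  residue the decomposition produces; this makes self-handling and
  duplicate-point behaviour exact.
- Tie rule, everywhere: ascending (distance, neighbour index). This
  total order is what makes every downstream result — including merge
  order and worker count — irrelevant to the output.
- Zero-norm columns are an input error for cosine/Pearson (the cosine
  is undefined); non-finite entries are an input error naming the
  offending column.

## Batch index sort

Each block's per-row *and* per-column top-k are extracted in one
batched procedure: sort all (distance, row, col) triples by distance,
then stable re-sort by column index, then (separately) stable re-sort
by row index. Stability carries the distance order into each group,
and because the block is laid out row-major, equal distances resolve to
ascending neighbour index with no explicit tie handling. The first k
entries of each group are the answer; groups are contiguous with fixed
extent, so extraction is a reshape. Any stable sort satisfies the
contract (numpy's stable argsort here); the choice of sort algorithm is
a tactic, not part of the contract. The naive per-row/per-column full
sort is kept as `per_axis_topk_oracle`, used only to verify the batched
path, ties included.

The triple array is materialised per block only; its size is bounded by
the partition planner, never by N².

## Scheduling and merging

Only upper-triangular blocks (q ≤ r) are computed, block-row by
block-row; D_qr's row k-NNs feed partition q and its column k-NNs feed
partition r (D_rq = D_qrᵀ yields them for free). Diagonal blocks feed
through rows only — their column lists coincide by transpose — and
over-select by one entry so the self-pair can be masked when
self-neighbours are excluded (the default; `include_self` flips it, and
then every query's rank-1 neighbour is itself at distance 0).

Candidates accumulate in bounded k-best structures ordered by the tie
rule. Their merge is commutative, associative and idempotent, so the
graph is a pure function of the block set, not of execution order: a
thread pool may execute blocks in any interleaving, and at fixed p the
output is bitwise reproducible across worker counts. Across different
p the neighbour index sets are identical but distances may differ in
the last ulp, because block boundaries change the summation order
inside the matrix product; the engine promises rtol 1e-12 there, not
bitwise equality. Two realisations of the accumulator exist: a scalar
per-query `KBest` (the normative reference for the algebra) and the
vectorised `KBestTable` the engine uses, which applies the same
operation row-wise; tests assert they agree fold-for-fold. Duplicate
(query, neighbour) sightings cannot arise from correct
upper-triangular scheduling, but both structures dedupe defensively
and count such events as a scheduling-bug canary (asserted zero in
engine runs).

Work accounting: the evaluation counter records *unique unordered
pairs* — off-diagonal blocks contribute rows × cols, diagonal blocks
w(w+1)/2 (their mirrored halves are the same pairs) — so a correct run
totals exactly N(N+1)/2 regardless of p, which the counters assert.

## Partition planning and memory model

p is the smallest multiple of the node count n whose per-node footprint
fits the node RAM budget. The footprint model is six terms: the
resident partition (d·⌈N/p⌉·s bytes), a double-buffered streamed chunk
(2·d·chunk·s), the row k-NN buffer (⌈N/p⌉·k·e), block-column k-NN
storage (⌈p/n⌉·⌈N/p⌉·k·e), per-worker partial column k-NNs
(g·⌈N/p⌉·k·e), and an OS reserve — with s the scalar width and
e = scalar + index width of one (distance, index) entry. The chunk
width is the largest satisfying the worker relation
`d·rows_per_worker·s + d·chunk·s + rows_per_worker·k·e ≤ worker budget`.
This cost model is a term-by-term reconstruction from a prose
description rather than a verbatim formula, so every term carries a
scale factor and can be re-weighted or disabled; the planner's
*minimality* (smallest feasible multiple, cross-checked by direct
evaluation of the cost function) is the tested contract, not the
constants. Ceiling effects make the cost non-monotone by ±1 element
between arbitrary p; over partition counts dividing N it is monotone
non-increasing, which is the regime the monotonicity test covers.

The node × worker hierarchy (n nodes, g workers each) is flattened to
n·g schedulable workers — at desk scale the hierarchy affects budgets,
not results, which the determinism tests confirm — while the memory
model keeps both levels. Blocks within a block row go to worker
`(r − q) mod n_workers`; the global merge of block row q is owned by
worker `q mod n_workers`. Partition boundaries are half-open, 0-based,
near-equal (trailing ranges one smaller, no padding).

At run time the engine additionally caps the streamed chunk so the
resident distance block (partition width × chunk × scalar bytes) never
exceeds the worker budget; an instrumented peak-bytes counter verifies
the ceiling in every streamed run. Streaming holds at most two source
chunks (one being consumed, one read ahead).

## Synthetic data

`generate_synthetic` emulates the target application — large clouds of
molecular images such as simulated diffraction snapshots of a molecule
in a handful of conformations — as an isotropic Gaussian mixture:
component identity stands for the conformation, `noise_sd` (default 1)
for shot-to-shot variation, and `component_separation` (default 10) for
the typical Euclidean distance between conformation centroids
(component means are drawn with scale `separation / sqrt(2d)` so the
*expected* inter-mean distance equals the parameter). Defaults are 10
components in 64 dimensions. Generation is a pure function of the spec
including its seed.

What the emulation does not capture: pixel-level correlations, Poisson
detector statistics, intensity normalisation artefacts, and the
curved low-dimensional manifold structure of real conformational
continua. Passing tests therefore certify the *graph construction* —
exactness, determinism, memory behaviour — on clouds with realistic
dimension and cluster structure; they say nothing about the downstream
embedding quality on real images, which depends on data properties the
mixture does not model.

## Problem sizes and verification

The test suite certifies oracle equivalence on a grid
N ∈ {64, 512, 2048} × d ∈ {4, 64, 512} × k ∈ {1, 8, 32} over all three
metrics, p ∈ {1, 3, 5} and 1 or 4 workers, plus a large-k run
(N = 4096, d = 256, k = 150, p = 4); these sizes exercise every
streaming and scheduling path while keeping a full-matrix reference
cheap to compute. The reference oracle materialises all N² distances
via per-pair evaluation (no Gram decomposition) and selects by direct
sort; agreement is exact on neighbour indices and rtol 1e-9 on
distances. The acceptance script runs N = 2048, d = 64, k = 32 with a
deliberately small worker budget so that column streaming is active in
the measured run.

## Known limitations

- Dense input only; no sparse matrices or non-metric similarities.
- Single-host execution: "nodes" and "workers" are a scheduling and
  memory model, not a transport; there is no fault tolerance or
  checkpointing.
- O(N·k) accumulator memory and an O(N²) reference path in
  `validate`/`brute_force_knng` bound the practical validation size,
  not the build itself.
- The per-block triple sort is O(bc log bc); a radix sort on float keys
  would be faster at GPU scale but is deliberately out of contract.
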