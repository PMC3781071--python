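"""Partition planning: block layout, worker schedule, memory model.

The N x N squared-distance matrix is split into p x p blocks; by
symmetry only the p(p+1)/2 upper-triangular blocks (q <= r) are
computed, each feeding neighbour candidates to both of its partitions.
Blocks within a block row are dealt to workers cyclically for load
balance, and the partition count p is the smallest multiple of the node
count n whose per-node memory footprint fits the node RAM budget.

The memory-cost model is reconstructed term by term from the prose
description of the node and worker RAM relations (the size of the
resident partition, a double-buffered streamed chunk, row and column
k-NN buffers, per-worker partial column k-NNs, and an OS reserve); each
term carries a scale factor so alternative readings of the budget
remain expressible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

__all__ = [
    "MemoryModel",
    "PartitionPlan",
    "InfeasibleBudgetError",
    "make_partition_plan",
    "block_schedule",
    "assign_block",
    "node_cost",
    "worker_chunk_cols",
]

#: node-cost term names, in the order they appear in the model
COST_TERMS = (
    "resident_partition",   # d * ceil(N/p) * s          — G_q held in RAM
    "stream_buffers",       # 2 * d * chunk_cols * s     — double-buffered G_r chunk
    "row_knn_buffer",       # ceil(N/p) * k * e          — row k-NN tuples
    "col_knn_storage",      # ceil(p/n) * ceil(N/p) * k * e — per-column heaps
    "worker_partials",      # g * ceil(N/p) * k * e      — per-worker column k-NNs
    "os_reserve",
)


class InfeasibleBudgetError(ValueError):
    """No partition count within range satisfies the memory budgets."""


@dataclass(frozen=True)
class MemoryModel:
    """Byte budgets and element sizes for the partition planner.

    ``scalar_bytes`` is the width of one distance/data scalar (8 for
    float64); ``index_bytes`` the width of one neighbour index; a k-NN
    entry is a (distance, index) tuple of ``scalar_bytes + index_bytes``.
    ``g`` is the number of workers per node.
    """

    node_budget_bytes: int
    worker_budget_bytes: int
    scalar_bytes: int = 8
    index_bytes: int = 8
    os_reserve_bytes: int = 0
    g: int = 1

    def __post_init__(self) -> None:
        for name in ("node_budget_bytes", "worker_budget_bytes",
                     "scalar_bytes", "index_bytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.os_reserve_bytes < 0 or self.os_reserve_bytes >= self.node_budget_bytes:
            raise ValueError("os_reserve_bytes must lie in [0, node_budget)")
        if self.g < 1:
            raise ValueError("g must be >= 1")

    @property
    def entry_bytes(self) -> int:
        return self.scalar_bytes + self.index_bytes


@dataclass(frozen=True)
class PartitionPlan:
    """Complete layout of one k-NNG run.

    ``boundaries`` are p disjoint half-open global column ranges covering
    [0, N); ``assignment`` maps every upper-triangular block (q, r),
    q <= r, to a worker id in [0, n_workers); ``chunk_cols`` is the
    streaming width for the column partition of each block.
    """

    p: int
    boundaries: tuple[tuple[int, int], ...]
    n_workers: int
    assignment: dict[tuple[int, int], int]
    chunk_cols: int
    mem: MemoryModel | None = None

    @property
    def N(self) -> int:
        return self.boundaries[-1][1]

    def partition_width(self, q: int) -> int:
        lo, hi = self.boundaries[q]
        return hi - lo

    @classmethod
    def regular(cls, N: int, p: int = 1, n_workers: int = 1,
                chunk_cols: int | None = None,
                mem: MemoryModel | None = None) -> "PartitionPlan":
        """Unconstrained plan: p near-equal ranges, cyclic assignment,
        full-width chunks unless ``chunk_cols`` is given."""
        if not 1 <= p <= N:
            raise ValueError(f"p must be in [1, N]; got p={p}, N={N}")
        bounds = _split_ranges(N, p)
        width = bounds[0][1] - bounds[0][0]
        assignment = {
            (q, r): assign_block(q, r, n_workers)
            for q in range(p) for r in range(q, p)
        }
        return cls(p, bounds, n_workers, assignment,
                   chunk_cols if chunk_cols else width, mem)


def _split_ranges(N: int, p: int) -> tuple[tuple[int, int], ...]:
    """p near-equal half-open ranges; the trailing ranges are one smaller
    when p does not divide N (no padding)."""
    base, extra = divmod(N, p)
    bounds = []
    start = 0
    for i in range(p):
        width = base + (1 if i < extra else 0)
        bounds.append((start, start + width))
        start += width
    return tuple(bounds)


def worker_chunk_cols(N: int, d: int, k: int, p: int, mem: MemoryModel) -> int:
    """Largest streaming chunk width fitting the worker RAM relation.

    The worker holds its share of the resident partition
    (``d * rows_per_worker * s``), one chunk of the streamed partition
    (``d * chunk_cols * s``) and its partial row k-NNs
    (``rows_per_worker * k * e``); returns 0 when even a single column
    does not fit.
    """
    width = ceil(N / p)
    rows_per_worker = ceil(width / mem.g)
    s, e = mem.scalar_bytes, mem.entry_bytes
    fixed = d * rows_per_worker * s + rows_per_worker * k * e
    free = mem.worker_budget_bytes - fixed
    if free < d * s:
        return 0
    return min(width, free // (d * s))


def node_cost(N: int, d: int, k: int, p: int, n: int, mem: MemoryModel,
              chunk_cols: int | None = None,
              term_scales: dict[str, float] | None = None) -> float:
    """Per-node RAM footprint of a p-way partitioning, in bytes.

    Sum of the six model terms (see :data:`COST_TERMS`); ``term_scales``
    scales or disables individual terms by name.
    """
    width = ceil(N / p)
    if chunk_cols is None:
        chunk_cols = worker_chunk_cols(N, d, k, p, mem)
    s, e = mem.scalar_bytes, mem.entry_bytes
    terms = {
        "resident_partition": d * width * s,
        "stream_buffers": 2 * d * chunk_cols * s,
        "row_knn_buffer": width * k * e,
        "col_knn_storage": ceil(p / n) * width * k * e,
        "worker_partials": mem.g * width * k * e,
        "os_reserve": mem.os_reserve_bytes,
    }
    scales = term_scales or {}
    return float(sum(v * scales.get(name, 1.0) for name, v in terms.items()))


def make_partition_plan(N: int, d: int, k: int, n: int, g: int,
                        mem: MemoryModel,
                        term_scales: dict[str, float] | None = None
                        ) -> PartitionPlan:
    """Choose the smallest feasible partition count and build the plan.

    p is the smallest multiple of the node count n (with p <= N) whose
    node cost fits ``mem.node_budget_bytes``; the chunk width is the
    largest satisfying the worker relation at that p.  Workers are
    flattened to ``n_workers = n * g`` for scheduling.
    """
    if n < 1 or g < 1 or k < 1:
        raise ValueError("n, g, k must all be >= 1")
    if N < n:
        raise ValueError(f"need N >= n, got N={N}, n={n}")
    if mem.g != g:
        mem = MemoryModel(mem.node_budget_bytes, mem.worker_budget_bytes,
                          mem.scalar_bytes, mem.index_bytes,
                          mem.os_reserve_bytes, g)
    best_cost = None
    for p in range(n, N + 1, n):
        chunk = worker_chunk_cols(N, d, k, p, mem)
        if chunk < 1:
            continue
        cost = node_cost(N, d, k, p, n, mem, chunk, term_scales)
        best_cost = cost if best_cost is None else min(best_cost, cost)
        if cost <= mem.node_budget_bytes:
            return PartitionPlan(
                p=p,
                boundaries=_split_ranges(N, p),
                n_workers=n * g,
                assignment={
                    (q, r): assign_block(q, r, n * g)
                    for q in range(p) for r in range(q, p)
                },
                chunk_cols=chunk,
                mem=mem,
            )
    if best_cost is None:
        raise InfeasibleBudgetError(
            "worker budget cannot hold a single streamed column at any "
            f"partition count p <= N={N}; need at least "
            f"{(d * mem.scalar_bytes)} bytes free per column"
        )
    raise InfeasibleBudgetError(
        f"no multiple of n={n} up to N={N} fits the node budget "
        f"{mem.node_budget_bytes} bytes; minimum achievable cost is "
        f"{best_cost:.0f} bytes"
    )


def block_schedule(plan: PartitionPlan) -> list[tuple[int, int]]:
    """Upper-triangular blocks in block-row order:
    (0,0) (0,1) ... (0,p-1) (1,1) ... (p-1,p-1)."""
    return [(q, r) for q in range(plan.p) for r in range(q, plan.p)]


def assign_block(q: int, r: int, n_workers: int) -> int:
    """Cyclic worker assignment within a block row.

    Worker ``(r - q) mod n_workers`` processes block (q, r); the global
    merge for block row q is owned by worker ``q mod n_workers``.
    Deterministic, and balanced within one block per worker per row.
    """
    if not 0 <= q <= r:
        raise ValueError(f"need 0 <= q <= r, got ({q}, {r})")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    return (r - q) % n_workers
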