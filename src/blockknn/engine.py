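"""Blockwise k-NNG construction engine.

Builds the exact k-nearest-neighbour graph of a column-vector cloud by
iterating the upper-triangular blocks of the (implicit) pairwise
distance matrix: each block D_qr is assembled from one Gram product and
the precomputed norm vector, its per-row and per-column k-NNs are
extracted by batch index sort, and both feed bounded k-best accumulators
— rows for the queries of partition q, columns for partition r (the
symmetric saving: D_qr = D_rq^T, so one block serves two partitions).
Diagonal blocks contribute through rows only.

Workers process disjoint sets of blocks; because the k-best merge
algebra is commutative, associative and idempotent, the result is
independent of worker count and block execution order, and bitwise
reproducible at fixed p.  Column streaming bounds the resident distance
block to the worker memory budget.
"""

from __future__ import annotations

import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import metrics
from .merging import KBestTable
from .metrics import DataMatrix, DistanceBlock, METRICS
from .partitioning import InfeasibleBudgetError, PartitionPlan, block_schedule
from .selection import batch_index_sort

__all__ = ["KNNGraph", "RunStats", "build_knng", "process_block",
           "stream_columns", "brute_force_knng"]


@dataclass
class RunStats:
    """Instrumentation for one build: work, memory and canary counters.

    Counter updates go through :meth:`bump`/:meth:`peak`, which are
    serialised by an internal lock so concurrent workers cannot lose
    increments.
    """

    blocks_computed: int = 0
    pairwise_evaluations: int = 0   # unique (unordered) pairs evaluated
    peak_block_bytes: int = 0       # largest resident distance block
    chunks_streamed: int = 0
    dedupe_events: int = 0
    block_seconds: dict[tuple[int, int], float] = field(default_factory=dict)
    elapsed_seconds: float = 0.0

    def __post_init__(self) -> None:
        self._lock = threading.Lock()

    def bump(self, name: str, amount: int = 1) -> None:
        with self._lock:
            setattr(self, name, getattr(self, name) + amount)

    def peak(self, name: str, value: int) -> None:
        with self._lock:
            setattr(self, name, max(getattr(self, name), value))

    def as_dict(self) -> dict:
        return {
            "blocks_computed": self.blocks_computed,
            "pairwise_evaluations": self.pairwise_evaluations,
            "peak_block_bytes": self.peak_block_bytes,
            "chunks_streamed": self.chunks_streamed,
            "dedupe_events": self.dedupe_events,
            "elapsed_seconds": self.elapsed_seconds,
        }


@dataclass
class KNNGraph:
    """Exact k-NN graph: for each of N queries, its k nearest neighbours.

    ``neighbor_ids[i]``/``distances[i]`` are ascending by
    (distance, neighbour id).  Euclidean distances are reported in true
    (non-squared) units; cosine and Pearson distances as defined.
    """

    N: int
    k: int
    neighbor_ids: np.ndarray
    distances: np.ndarray
    metric: str
    self_excluded: bool
    stats: RunStats | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KNNGraph):
            return NotImplemented
        return (
            self.N == other.N and self.k == other.k
            and self.metric == other.metric
            and self.self_excluded == other.self_excluded
            and np.array_equal(self.neighbor_ids, other.neighbor_ids)
            and np.array_equal(self.distances, other.distances)
        )


def stream_columns(source, chunk_cols: int,
                   stats: RunStats | None = None) -> Iterator[tuple[int, np.ndarray]]:
    """Yield consecutive column chunks ``(start, array)`` of a d x N source.

    ``source`` is anything sliceable along axis 1 (an ndarray or an HDF5
    dataset).  One chunk is read ahead while the previous is consumed,
    so at most two chunks of source data are ever resident (double
    buffering); I/O errors are re-raised with the failing column range.
    """
    if chunk_cols < 1:
        raise ValueError(f"chunk_cols must be >= 1, got {chunk_cols}")
    n = source.shape[1]
    starts = list(range(0, n, chunk_cols))

    def read(start: int) -> np.ndarray:
        stop = min(start + chunk_cols, n)
        try:
            return np.asarray(source[:, start:stop])
        except Exception as exc:  # pragma: no cover - I/O context only
            raise IOError(f"failed reading columns [{start}, {stop}): {exc}") from exc

    if not starts:
        return
    buffer = read(starts[0])  # one chunk ahead of the consumer
    for i, start in enumerate(starts):
        current, buffer = buffer, None
        if i + 1 < len(starts):
            buffer = read(starts[i + 1])
        if stats is not None:
            stats.bump("chunks_streamed")
        yield start, current


def _resolve_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    return metric


def process_block(q: int, r: int, plan: PartitionPlan, X: DataMatrix,
                  norms: np.ndarray, table: KBestTable, metric: str,
                  include_self: bool, k: int, stats: RunStats,
                  lock: threading.Lock | None = None) -> None:
    """Compute block D_qr once and route its k-NNs into the accumulators.

    Row k-NNs feed the queries of partition q; column k-NNs feed
    partition r.  Diagonal blocks (q == r) feed through rows only — their
    column k-NNs coincide by transpose — and over-select by one so that
    the self-pair can be masked when self-neighbours are excluded.
    The block is materialised at most ``chunk_cols`` columns at a time.
    """
    t0 = time.perf_counter()
    q_lo, q_hi = plan.boundaries[q]
    r_lo, r_hi = plan.boundaries[r]
    Xq = X.column_slice(q_lo, q_hi)
    nu_q = norms[q_lo:q_hi]
    diagonal = q == r
    k_sel = k + 1 if (diagonal and not include_self) else k
    scalar_bytes = X.values.dtype.itemsize

    chunk_cols = plan.chunk_cols
    if plan.mem is not None:
        # cap the resident distance block at the worker budget
        cap = plan.mem.worker_budget_bytes // ((q_hi - q_lo) * scalar_bytes)
        if cap < 1:
            raise InfeasibleBudgetError(
                "worker budget cannot hold one distance column for "
                f"partition width {q_hi - q_lo}"
            )
        chunk_cols = min(chunk_cols, cap)

    for start, chunk in stream_columns(X.values[:, r_lo:r_hi], chunk_cols, stats):
        Xr = DataMatrix(chunk, col_offset=r_lo + start)
        nu_r = norms[Xr.col_offset:Xr.col_offset + Xr.N]
        if metric == "euclidean":
            gram = metrics.gram_block(Xq, Xr)
            block = metrics.euclidean_sq_block(gram, nu_q, nu_r,
                                               q_lo, Xr.col_offset)
        else:
            tag = "cosine" if metric == "cosine" else "pearson"
            block = metrics.cosine_block(Xq, Xr, nu_q, nu_r,
                                         q_lo, Xr.col_offset, tag)
        nrows, ncols = block.shape
        block_bytes = nrows * ncols * scalar_bytes
        knns = batch_index_sort(block, k_sel,
                                axes="rows" if diagonal else "both")
        if lock is None:
            _apply_block_knns(table, block, knns, diagonal, include_self, stats,
                              block_bytes)
        else:
            with lock:
                _apply_block_knns(table, block, knns, diagonal, include_self,
                                  stats, block_bytes)
    stats.block_seconds[(q, r)] = time.perf_counter() - t0
    stats.bump("blocks_computed")


def _apply_block_knns(table: KBestTable, block: DistanceBlock, knns,
                      diagonal: bool, include_self: bool, stats: RunStats,
                      block_bytes: int) -> None:
    nrows, ncols = block.shape
    stats.peak("peak_block_bytes", block_bytes)
    if diagonal:
        # a diagonal block mirrors each unordered pair across its main
        # diagonal; count only the pairs (i, j), i <= j, whose column j
        # falls in this chunk, so the whole block sums to w(w+1)/2
        jlo = block.col_offset - block.row_offset
        unique = ncols * (jlo + 1) + ncols * (ncols - 1) // 2
        stats.bump("pairwise_evaluations", unique)
    else:
        stats.bump("pairwise_evaluations", nrows * ncols)
    exclude = diagonal and not include_self
    table.update(block.row_offset, knns.row_ids, knns.row_dists,
                 exclude_query=exclude)
    if not diagonal:
        table.update(block.col_offset, knns.col_ids, knns.col_dists)


def build_knng(X: DataMatrix, k: int, metric: str = "euclidean",
               plan: PartitionPlan | None = None, *, p: int | None = None,
               n_workers: int = 1, include_self: bool = False,
               precision: str = "64", pearson_centering: str = "dataset",
               ) -> KNNGraph:
    """Build the exact k-NN graph of a column-vector cloud.

    Parameters
    ----------
    X
        Input cloud, one vector per column.
    k
        Neighbour count; must satisfy ``k <= N - 1`` when self-neighbours
        are excluded (default) or ``k <= N`` when included.
    metric
        ``"euclidean"``, ``"cosine"`` or ``"pearson"``.  Euclidean
        selection runs on squared distances (monotone-equivalent) and
        reports true Euclidean distances in the result.
    plan, p, n_workers
        Either a full :class:`~blockknn.partitioning.PartitionPlan` or a
        partition count ``p`` (default 1) with a worker count; the result
        is independent of both, by the merge algebra.
    precision
        ``"64"`` (default; the basis of all stated tolerances) or
        ``"32"`` for scale experiments.
    pearson_centering
        ``"dataset"`` subtracts the dataset mean vector (centred-cosine
        convention); ``"per_vector"`` gives textbook per-vector Pearson.

    Returns the :class:`KNNGraph` with :class:`RunStats` attached.
    """
    metric = _resolve_metric(metric)
    N = X.N
    k_max = N if include_self else N - 1
    if not 1 <= k <= k_max:
        raise ValueError(
            f"k must be in [1, {k_max}] for N={N} "
            f"(self {'included' if include_self else 'excluded'}); got {k}"
        )
    if plan is None:
        plan = PartitionPlan.regular(N, p=p or 1, n_workers=n_workers)
    elif p is not None and p != plan.p:
        raise ValueError("give either a plan or p, not conflicting both")
    if plan.N != N:
        raise ValueError(f"plan covers N={plan.N}, data has N={N}")

    dtype = {"64": np.float64, "32": np.float32}.get(str(precision))
    if dtype is None:
        raise ValueError(f"precision must be '64' or '32', got {precision!r}")
    Xw = X if X.values.dtype == dtype else DataMatrix(
        X.values.astype(dtype), X.col_offset)
    if metric == "pearson":
        Xw = metrics.center_data(Xw, mode=pearson_centering)
    norms = metrics.compute_norms(Xw)
    if metric in ("cosine", "pearson"):
        metrics._check_nonzero_norms(norms, 0, metric)

    stats = RunStats()
    t0 = time.perf_counter()
    table = KBestTable(N, k, offset=0, n_total=N, dtype=dtype)
    by_worker: dict[int, list[tuple[int, int]]] = {}
    for (q, r) in block_schedule(plan):
        by_worker.setdefault(plan.assignment[(q, r)], []).append((q, r))

    def run_worker(blocks: list[tuple[int, int]],
                   lock: threading.Lock | None) -> None:
        for (q, r) in blocks:
            process_block(q, r, plan, Xw, norms, table, metric,
                          include_self, k, stats, lock)

    workers = sorted(by_worker)
    if len(workers) <= 1:
        run_worker(by_worker[workers[0]], None)
    else:
        lock = threading.Lock()
        with ThreadPoolExecutor(max_workers=len(workers)) as pool:
            futures = [pool.submit(run_worker, by_worker[w], lock)
                       for w in workers]
            for f in futures:
                f.result()  # re-raise worker errors

    stats.dedupe_events += table.dedupe_events
    if (table.lengths() < k).any():
        short = int(np.nonzero(table.lengths() < k)[0][0])
        raise RuntimeError(f"query {short} ended with fewer than k neighbours")
    ids = table.ids.copy()
    dists = table.dists.copy()
    if metric == "euclidean":
        np.sqrt(dists, out=dists)  # report true distances; order unchanged
    stats.elapsed_seconds = time.perf_counter() - t0
    return KNNGraph(N=N, k=k, neighbor_ids=ids, distances=dists,
                    metric=metric, self_excluded=not include_self,
                    stats=stats)


def brute_force_knng(X: DataMatrix, k: int, metric: str = "euclidean",
                     include_self: bool = False,
                     pearson_centering: str = "dataset") -> KNNGraph:
    """One-shot full-matrix reference build, bypassing the block pipeline.

    Materialises the whole N x N distance matrix through the per-pair
    oracle (no Gram decomposition, no blocking, no batch index sort) and
    selects neighbours by direct per-row sort under the same tie rule.
    Validation/oracle use only: O(N^2) memory.
    """
    metric = _resolve_metric(metric)
    N = X.N
    Xc = metrics.center_data(X, pearson_centering) if metric == "pearson" else X
    tag = "euclidean_sq" if metric == "euclidean" else metric
    full = metrics.direct_distance_oracle(Xc, Xc, tag).values
    if not include_self:
        np.fill_diagonal(full, np.inf)
    idx = np.arange(N)[None, :].repeat(N, axis=0)
    order = np.lexsort((idx, full))[:, :k]
    dists = np.take_along_axis(full, order, axis=1)
    if metric == "euclidean":
        dists = np.sqrt(dists)
    return KNNGraph(N=N, k=k, neighbor_ids=order.astype(np.int64),
                    distances=dists, metric=metric,
                    self_excluded=not include_self)
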