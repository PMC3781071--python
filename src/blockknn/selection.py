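"""Batched top-k selection over distance blocks (batch index sort).

Selecting the k smallest entries of every row and every column of a
block is done in one three-pass scheme rather than row-by-row:

1. sort all (distance, row, col) triples of the block by distance;
2. stable re-sort of the pass-1 order by column index — the first k
   entries of each column group are that column's k-NNs;
3. stable re-sort of the pass-1 order by row index — the first k
   entries of each row group are that row's k-NNs.

Because the block is laid out row-major and the sorts are stable, ties
resolve to ascending neighbour index automatically, giving the global
deterministic tie rule: ascending (distance, neighbour index).

``per_axis_topk_oracle`` is the deliberately naive reference (full sort
of each row/column independently) kept for verification only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .metrics import DistanceBlock

__all__ = ["IndexedDistance", "BlockKNNs", "batch_index_sort", "per_axis_topk_oracle"]


class IndexedDistance(NamedTuple):
    """One block entry carrying its global row and column indices."""

    distance: float
    row: int
    col: int


@dataclass
class BlockKNNs:
    """Per-row and per-column k-NNs of one block, in global indices.

    ``row_ids[i]`` lists the global *column* indices of the k nearest
    columns to block row ``i``; ``col_ids[j]`` the global *row* indices
    nearest to block column ``j``.  Each list is ascending by
    (distance, index); widths are ``min(k, opposite extent)``.
    ``col_ids``/``col_dists`` are ``None`` when only the row axis was
    requested (diagonal-block fast path, where columns coincide with
    rows by transpose).
    """

    row_ids: np.ndarray
    row_dists: np.ndarray
    col_ids: np.ndarray | None
    col_dists: np.ndarray | None


def batch_index_sort(block: DistanceBlock, k: int, axes: str = "both") -> BlockKNNs:
    """Top-k of every row and column of ``block`` via the three-pass sort.

    Parameters
    ----------
    block
        Distance block with global offsets.
    k
        Neighbour count; sequences are truncated to the opposite extent
        when ``k`` exceeds it (the engine enforces global feasibility).
    axes
        ``"both"`` (default) or ``"rows"`` for the diagonal-block fast
        path that skips the column pass.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if axes not in ("both", "rows"):
        raise ValueError(f"axes must be 'both' or 'rows', got {axes!r}")
    vals = block.values
    b, c = vals.shape
    if b == 0 or c == 0:
        raise ValueError("empty distance block")
    flat = vals.ravel()

    # pass 1: order all triples by distance (stable => row-major flat
    # order, i.e. ascending (row, col), survives among equal distances)
    order1 = np.argsort(flat, kind="stable")

    # pass 3: stable re-sort by row index; each row group is contiguous
    # with exactly c entries, so a reshape exposes the groups
    order_rows = order1[np.argsort(order1 // c, kind="stable")]
    kr = min(k, c)
    row_top = order_rows.reshape(b, c)[:, :kr]
    row_ids = row_top % c + block.col_offset
    row_dists = flat[row_top]

    if axes == "rows":
        return BlockKNNs(row_ids, row_dists, None, None)

    # pass 2: stable re-sort by column index
    order_cols = order1[np.argsort(order1 % c, kind="stable")]
    kc = min(k, b)
    col_top = order_cols.reshape(c, b)[:, :kc]
    col_ids = col_top // c + block.row_offset
    col_dists = flat[col_top]
    return BlockKNNs(row_ids, row_dists, col_ids, col_dists)


def per_axis_topk_oracle(block: DistanceBlock, k: int, axis: str) -> BlockKNNs:
    """Ground-truth top-k by full independent sort of each row or column.

    Test oracle only: plain Python sort of ``IndexedDistance`` triples per
    line, under the same (distance, neighbour index) tie rule.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    vals = block.values
    b, c = vals.shape
    if axis == "rows":
        kk = min(k, c)
        ids = np.empty((b, kk), dtype=np.int64)
        dists = np.empty((b, kk), dtype=vals.dtype)
        for i in range(b):
            triples = sorted(
                IndexedDistance(vals[i, j], i + block.row_offset, j + block.col_offset)
                for j in range(c)
            )[:kk]
            ids[i] = [t.col for t in triples]
            dists[i] = [t.distance for t in triples]
        return BlockKNNs(ids, dists, None, None)
    if axis == "cols":
        kk = min(k, b)
        ids = np.empty((c, kk), dtype=np.int64)
        dists = np.empty((c, kk), dtype=vals.dtype)
        for j in range(c):
            triples = sorted(
                (vals[i, j], i + block.row_offset)  # (distance, neighbour row)
                for i in range(b)
            )[:kk]
            ids[j] = [t[1] for t in triples]
            dists[j] = [t[0] for t in triples]
        return BlockKNNs(np.empty((b, 0), np.int64), np.empty((b, 0)), ids, dists)
    raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
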