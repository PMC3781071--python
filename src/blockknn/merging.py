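"""Bounded k-best accumulators and their order-independent merge algebra.

Every query owns an accumulator holding the k smallest
(neighbour id, distance) pairs seen so far, totally ordered by
ascending (distance, neighbour id).  The merge of two accumulators is
commutative, associative and idempotent, so the global k-NN result is
independent of block processing order and worker count — this algebra
replaces inter-node heap exchange with in-process result passing.

Two realisations share the contract:

* :class:`KBest` — a per-query sorted bounded sequence with
  :func:`kbest_push` / :func:`kbest_merge`; the normative reference.
* :class:`KBestTable` — a vectorised accumulator for a contiguous range
  of queries, used by the engine hot path; its updates are the same
  algebra applied row-wise with numpy.

Duplicate (query, neighbour) pairs cannot arise from correct
upper-triangular scheduling, but both realisations dedupe defensively
(keeping the minimum distance) and count dedupe events as a
scheduling-bug canary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["KBest", "kbest_push", "kbest_merge", "KBestTable", "MergeError"]

_PAD_ID = -1  # empty slot sentinel in KBestTable (distance = +inf)


class MergeError(ValueError):
    """Raised for incompatible or invalid merge inputs."""


@dataclass(frozen=True)
class KBest:
    """The k best (neighbour id, distance) pairs for one query.

    Entries are ascending by (distance, neighbour id), at most
    ``capacity`` of them, with no duplicate neighbour ids.  ``n_total``
    optionally bounds valid neighbour ids to ``[0, n_total)``.
    """

    query_id: int
    capacity: int
    entries: tuple[tuple[int, float], ...] = ()
    n_total: int | None = None
    dedupe_events: int = 0

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise MergeError(f"capacity must be >= 1, got {self.capacity}")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(e[1] for e in self.entries)


def kbest_push(acc: KBest, candidates: Iterable[tuple[int, float]]) -> KBest:
    """Fold candidate (neighbour id, distance) pairs into an accumulator.

    Returns a new accumulator holding the k smallest of the union under
    the (distance, id) tie rule.  Duplicate neighbour ids collapse to
    their minimum distance, so pushing the same list twice is a no-op.
    """
    best: dict[int, float] = dict(
        (nid, d) for nid, d in ((int(n), float(d)) for n, d in acc.entries)
    )
    dedupes = acc.dedupe_events
    for nid, dist in candidates:
        nid = int(nid)
        dist = float(dist)
        if not np.isfinite(dist) or dist < 0.0:
            raise MergeError(
                f"invalid candidate distance {dist!r} for neighbour {nid}"
            )
        if acc.n_total is not None and not 0 <= nid < acc.n_total:
            raise MergeError(
                f"candidate id {nid} out of range [0, {acc.n_total})"
            )
        if nid in best:
            dedupes += 1
            if dist < best[nid]:
                best[nid] = dist
        else:
            best[nid] = dist
    merged = sorted(((d, nid) for nid, d in best.items()))[: acc.capacity]
    return KBest(
        query_id=acc.query_id,
        capacity=acc.capacity,
        entries=tuple((nid, d) for d, nid in merged),
        n_total=acc.n_total,
        dedupe_events=dedupes,
    )


def kbest_merge(a: KBest, b: KBest) -> KBest:
    """Top-k of the union of two accumulators for the same query."""
    if a.query_id != b.query_id:
        raise MergeError(f"query id mismatch: {a.query_id} vs {b.query_id}")
    if a.capacity != b.capacity:
        raise MergeError(f"capacity mismatch: {a.capacity} vs {b.capacity}")
    # entries within one accumulator are already deduped; common ids
    # across the two inputs are idempotent re-sightings, not canaries
    merged = kbest_push(a, b.entries)
    return KBest(
        query_id=merged.query_id,
        capacity=merged.capacity,
        entries=merged.entries,
        n_total=merged.n_total,
        dedupe_events=a.dedupe_events + b.dedupe_events,
    )


class KBestTable:
    """Vectorised k-best accumulators for queries ``[offset, offset + n)``.

    Internal layout: ``ids``/``dists`` arrays of shape ``(n, capacity)``
    padded with (-1, +inf); every row is kept ascending by
    (distance, id) so a finished table reads off directly as the k-NN
    result.  ``update`` applies the same merge algebra as
    :func:`kbest_push` to a batch of candidate lists in one shot.
    """

    def __init__(self, n: int, capacity: int, offset: int = 0,
                 n_total: int | None = None, dtype=np.float64) -> None:
        if capacity < 1:
            raise MergeError(f"capacity must be >= 1, got {capacity}")
        self.n = int(n)
        self.capacity = int(capacity)
        self.offset = int(offset)
        self.n_total = n_total
        self.ids = np.full((n, capacity), _PAD_ID, dtype=np.int64)
        self.dists = np.full((n, capacity), np.inf, dtype=dtype)
        self.dedupe_events = 0

    def update(self, first_query: int, cand_ids: np.ndarray,
               cand_dists: np.ndarray, exclude_query: bool = False) -> None:
        """Merge candidate lists for queries ``first_query, ... `` (global).

        ``cand_ids``/``cand_dists`` have one row per consecutive query.
        With ``exclude_query`` the candidate equal to the query's own id
        is masked out (self-neighbour suppression on diagonal blocks).
        """
        lo = first_query - self.offset
        m = cand_ids.shape[0]
        if lo < 0 or lo + m > self.n:
            raise MergeError(
                f"query range [{first_query}, {first_query + m}) outside table"
            )
        cand_ids = np.asarray(cand_ids, dtype=np.int64)
        cand_dists = np.asarray(cand_dists, dtype=self.dists.dtype)
        if self.n_total is not None:
            valid = (cand_ids >= 0) & (cand_ids < self.n_total)
            if not valid.all():
                bad = cand_ids[~valid][0]
                raise MergeError(f"candidate id {bad} out of range [0, {self.n_total})")
        if exclude_query:
            qids = np.arange(first_query, first_query + m)[:, None]
            mask = cand_ids == qids
            if mask.any():
                cand_ids = np.where(mask, _PAD_ID, cand_ids)
                cand_dists = np.where(mask, np.inf, cand_dists)

        ids = np.concatenate([self.ids[lo:lo + m], cand_ids], axis=1)
        dists = np.concatenate([self.dists[lo:lo + m], cand_dists], axis=1)
        # per-row sort by (distance, id); padding (+inf) sinks to the end
        order = np.lexsort((ids, dists))
        ids = np.take_along_axis(ids, order, axis=1)
        dists = np.take_along_axis(dists, order, axis=1)
        self._dedupe_rows(ids, dists)
        self.ids[lo:lo + m] = ids[:, : self.capacity]
        self.dists[lo:lo + m] = dists[:, : self.capacity]

    def _dedupe_rows(self, ids: np.ndarray, dists: np.ndarray) -> None:
        """Defensive in-place dedupe of (distance, id)-sorted rows."""
        by_id = np.sort(ids, axis=1)
        dup_rows = np.nonzero(
            ((by_id[:, 1:] == by_id[:, :-1]) & (by_id[:, 1:] >= 0)).any(axis=1)
        )[0]
        for r in dup_rows:
            seen: set[int] = set()
            for c in range(ids.shape[1]):
                nid = ids[r, c]
                if nid < 0:
                    continue
                if nid in seen:
                    # later duplicate has >= distance under the row order
                    ids[r, c] = _PAD_ID
                    dists[r, c] = np.inf
                    self.dedupe_events += 1
                else:
                    seen.add(int(nid))
            order = np.lexsort((ids[r], dists[r]))
            ids[r] = ids[r][order]
            dists[r] = dists[r][order]

    def lengths(self) -> np.ndarray:
        return (self.ids >= 0).sum(axis=1)

    def to_kbest(self, query_id: int) -> KBest:
        """Extract one query's accumulator as a :class:`KBest`."""
        r = query_id - self.offset
        filled = self.ids[r] >= 0
        return KBest(
            query_id=query_id,
            capacity=self.capacity,
            entries=tuple(
                (int(i), float(d))
                for i, d in zip(self.ids[r][filled], self.dists[r][filled])
            ),
            n_total=self.n_total,
        )
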