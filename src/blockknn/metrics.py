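"""Distance metrics on column-vector data, computed blockwise.

The central identity is the decomposition of squared Euclidean distances
into norms and inner products,

    d2(x, y) = ||x||^2 + ||y||^2 - 2 <x, y>,

so that a whole block of pairwise distances costs one dense matrix
product ``Xq^T Xr`` plus a rank-1 correction from the precomputed vector
of squared column norms.  Cosine distance is assembled from the same
Gram product, and Pearson distance is realised as cosine distance after
centring the data (dataset-mean centring by default).

Everything here is pure computation on in-memory arrays; the engine
decides block boundaries and streaming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DataMatrix",
    "DistanceBlock",
    "MetricError",
    "compute_norms",
    "gram_block",
    "euclidean_sq_block",
    "cosine_block",
    "pearson_block",
    "center_data",
    "direct_distance_oracle",
    "METRICS",
]

METRICS = ("euclidean", "cosine", "pearson")

#: metric tags carried by DistanceBlock (euclidean blocks hold *squared*
#: distances; the square root is taken only at graph write-out)
_BLOCK_TAGS = ("euclidean_sq", "cosine", "pearson")


class MetricError(ValueError):
    """Raised for invalid metric inputs (non-finite data, zero-norm columns)."""


@dataclass
class DataMatrix:
    """A cloud of ``N`` vectors in ``d`` dimensions, one vector per column.

    Parameters
    ----------
    values
        Dense real matrix of shape ``(d, N)``; column ``j`` is vector ``x_j``.
    col_offset
        Global index of the first column.  Partitions of a larger cloud
        keep their position in the global indexing through this offset.
    """

    values: np.ndarray
    col_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise MetricError(
                f"data matrix must be 2-D (d x N), got shape {self.values.shape}"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise MetricError(f"degenerate data matrix shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float64)
        bad = ~np.isfinite(self.values)
        if bad.any():
            col = int(np.nonzero(bad.any(axis=0))[0][0]) + self.col_offset
            raise MetricError(f"non-finite entry in data column {col}")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def column_slice(self, start: int, stop: int) -> "DataMatrix":
        """View of columns ``[start, stop)`` (local indices), offset-adjusted."""
        dm = object.__new__(DataMatrix)
        dm.values = self.values[:, start:stop]
        dm.col_offset = self.col_offset + start
        return dm


@dataclass
class DistanceBlock:
    """A dense sub-matrix of pairwise distances with global offsets.

    ``values[i, j]`` is the distance between global row vector
    ``row_offset + i`` and global column vector ``col_offset + j``.
    Euclidean blocks store squared distances (tag ``euclidean_sq``).
    """

    values: np.ndarray
    row_offset: int
    col_offset: int
    metric: str = "euclidean_sq"

    def __post_init__(self) -> None:
        if self.metric not in _BLOCK_TAGS:
            raise MetricError(f"unknown distance-block metric tag {self.metric!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_norms(X: DataMatrix) -> np.ndarray:
    """Squared Euclidean norm of every column, in one array reduction.

    Returns the length-``N`` vector ``nu`` with ``nu[j] = sum_i X[i, j]**2``.
    Computed once up front and reused for every block of the run.
    """
    return np.einsum("ij,ij->j", X.values, X.values)


def gram_block(Xq: DataMatrix, Xr: DataMatrix) -> np.ndarray:
    """Pairwise inner products ``<x_i, y_j>`` as one dense product ``Xq^T Xr``."""
    if Xq.d != Xr.d:
        raise MetricError(f"dimension mismatch: {Xq.d} vs {Xr.d}")
    return Xq.values.T @ Xr.values


def _zero_self_diagonal(values: np.ndarray, row_offset: int, col_offset: int) -> None:
    """Force exact zeros at global self-pairs (i == j) inside a block."""
    n_rows, n_cols = values.shape
    lo = max(row_offset, col_offset)
    hi = min(row_offset + n_rows, col_offset + n_cols)
    if hi > lo:
        idx = np.arange(lo, hi)
        values[idx - row_offset, idx - col_offset] = 0.0


def euclidean_sq_block(
    gram: np.ndarray,
    nu_q: np.ndarray,
    nu_r: np.ndarray,
    row_offset: int = 0,
    col_offset: int = 0,
) -> DistanceBlock:
    """Assemble squared Euclidean distances from a Gram block and norm slices.

    Entry ``(i, j)`` is ``max(0, nu_q[i] + nu_r[j] - 2 * gram[i, j])``; tiny
    negatives from floating-point cancellation are clamped to zero, and
    global self-pairs are pinned to exactly zero.
    """
    if gram.shape != (len(nu_q), len(nu_r)):
        raise MetricError(
            f"gram shape {gram.shape} does not match norm slices "
            f"({len(nu_q)}, {len(nu_r)})"
        )
    vals = nu_q[:, None] + nu_r[None, :] - 2.0 * gram
    np.maximum(vals, 0.0, out=vals)
    _zero_self_diagonal(vals, row_offset, col_offset)
    return DistanceBlock(vals, row_offset, col_offset, "euclidean_sq")


def _check_nonzero_norms(nu: np.ndarray, offset: int, what: str) -> None:
    zero = np.nonzero(nu == 0.0)[0]
    if zero.size:
        raise MetricError(
            f"{what} distance undefined for zero-norm vector in column "
            f"{int(zero[0]) + offset}"
        )


def cosine_block(
    Xq: DataMatrix,
    Xr: DataMatrix,
    nu_q: np.ndarray,
    nu_r: np.ndarray,
    row_offset: int = 0,
    col_offset: int = 0,
    metric_tag: str = "cosine",
) -> DistanceBlock:
    """Cosine distances ``1 - <x, y> / (||x|| ||y||)`` from the Gram product.

    Entries are clamped into [0, 2]; zero-norm columns are an error since
    the cosine is undefined for them.
    """
    _check_nonzero_norms(nu_q, row_offset, "cosine")
    _check_nonzero_norms(nu_r, col_offset, "cosine")
    gram = gram_block(Xq, Xr)
    vals = 1.0 - gram / np.sqrt(nu_q)[:, None] / np.sqrt(nu_r)[None, :]
    np.clip(vals, 0.0, 2.0, out=vals)
    _zero_self_diagonal(vals, row_offset, col_offset)
    return DistanceBlock(vals, row_offset, col_offset, metric_tag)


def pearson_block(
    Xq_centered: DataMatrix,
    Xr_centered: DataMatrix,
    nu_q: np.ndarray,
    nu_r: np.ndarray,
    row_offset: int = 0,
    col_offset: int = 0,
) -> DistanceBlock:
    """Pearson distance ``1 - r`` as cosine distance of centred data.

    The caller centres the whole dataset once with :func:`center_data`
    (dataset-mean centring by default) and passes the centred partitions
    with their norms; this is literally the cosine code path with a
    different tag, so the cosine/Pearson identity holds by construction.
    """
    return cosine_block(
        Xq_centered, Xr_centered, nu_q, nu_r, row_offset, col_offset, "pearson"
    )


def center_data(X: DataMatrix, mode: str = "dataset") -> DataMatrix:
    """Centre the cloud for Pearson distance.

    ``mode="dataset"`` (default) subtracts the dataset mean vector mu
    (per-dimension mean over all N columns) from every column, so Pearson
    becomes a centred cosine of the whole cloud.  ``mode="per_vector"``
    subtracts each column's own scalar mean across its components — the
    textbook correlation convention — for users who expect it.
    """
    if mode == "dataset":
        centred = X.values - X.values.mean(axis=1, keepdims=True)
    elif mode == "per_vector":
        centred = X.values - X.values.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown centering mode {mode!r}")
    return DataMatrix(centred, X.col_offset)


def direct_distance_oracle(
    Xq: DataMatrix,
    Xr: DataMatrix,
    metric: str = "euclidean_sq",
    row_offset: int = 0,
    col_offset: int = 0,
) -> DistanceBlock:
    """Reference pairwise distances computed without the Gram decomposition.

    Per-pair evaluation (scipy ``cdist``), used only for validation and
    tests: it shares no code with the blockwise path.  For Pearson, pass
    already-centred data with ``metric="cosine"`` and retag.
    """
    if Xq.d != Xr.d:
        raise MetricError(f"dimension mismatch: {Xq.d} vs {Xr.d}")
    if metric == "euclidean_sq":
        vals = cdist(Xq.values.T, Xr.values.T, metric="sqeuclidean")
    elif metric in ("cosine", "pearson"):
        _check_nonzero_norms(compute_norms(Xq), row_offset, "cosine")
        _check_nonzero_norms(compute_norms(Xr), col_offset, "cosine")
        vals = cdist(Xq.values.T, Xr.values.T, metric="cosine")
    else:
        raise MetricError(f"unknown metric {metric!r}")
    np.maximum(vals, 0.0, out=vals)
    _zero_self_diagonal(vals, row_offset, col_offset)
    return DistanceBlock(vals, row_offset, col_offset, metric)
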