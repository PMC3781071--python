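"""Shared fixtures and the test-side brute-force reference.

``oracle_knng`` is deliberately independent of the package's block
pipeline: it materialises the full pairwise distance matrix through
scipy's per-pair ``cdist`` and selects neighbours with a plain
lexicographic sort, so agreement with ``build_knng`` certifies the
Gram decomposition, the batch index sort, the scheduling and the merge
algebra all at once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist


def oracle_knng(values: np.ndarray, k: int, metric: str = "euclidean",
                include_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Full-matrix k-NN reference on a (d, N) array.

    Returns (neighbor_ids, distances), each (N, k), ascending by
    (distance, neighbour id).  Pearson uses dataset-mean centring.
    """
    pts = values.T
    if metric == "euclidean":
        full = cdist(pts, pts, metric="euclidean")
    elif metric == "cosine":
        full = cdist(pts, pts, metric="cosine")
    elif metric == "pearson":
        centred = pts - pts.mean(axis=0, keepdims=True)
        full = cdist(centred, centred, metric="cosine")
    else:
        raise ValueError(metric)
    np.maximum(full, 0.0, out=full)
    np.fill_diagonal(full, 0.0 if include_self else np.inf)
    n = full.shape[0]
    idx = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx, full))[:, :k]
    return order, np.take_along_axis(full, order, axis=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230923)


@pytest.fixture
def gaussian_cloud():
    """Seeded 32-dimensional Gaussian cloud of 120 points."""
    g = np.random.default_rng(7)
    return g.standard_normal((32, 120))
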