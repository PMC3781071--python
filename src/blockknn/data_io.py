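"""Readers, writers, and the synthetic point-cloud generator.

File conventions
----------------
* **Delimited text** — one vector per line (whitespace- or
  comma-delimited, optional header line skipped on request).  Files
  store vectors as rows because that is the natural dump of an image
  dataset; the in-memory :class:`~blockknn.metrics.DataMatrix` is
  column-per-vector, so the reader transposes.
* **Binary dense container** — magic ``BKNNMAT1``, one dtype byte
  (0 = float64, 1 = float32), little-endian int64 ``d`` and ``N``, then
  the column-major float payload.
* **HDF5** — dataset ``vectors`` of shape ``(N, d)`` (vectors as rows,
  mirroring the text layout).
* **k-NNG edge list** — TSV with header
  ``# query\trank\tneighbor\tdistance``; 0-based ids, distances printed
  with 17 significant digits so a 64-bit round trip is lossless.
* **MatrixMarket** — N x N sparse coordinate file with k entries per
  row, 1-based indices per that standard, distances as values.

The synthetic generator emulates high-dimensional molecular image
clouds — e.g. simulated diffraction snapshots of a molecule caught in a
handful of conformations — as an isotropic Gaussian mixture: cluster
identity models the conformation, ``noise_sd`` the shot-to-shot
variation, and ``component_separation`` the typical Euclidean distance
between conformation centroids.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.io
import scipy.sparse

from .engine import KNNGraph
from .metrics import DataMatrix

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "read_matrix",
    "write_matrix",
    "read_knng",
    "write_knng",
    "FormatError",
]

_MAGIC = b"BKNNMAT1"
_DTYPE_CODES = {0: np.float64, 1: np.float32}


class FormatError(ValueError):
    """Malformed or unrecognised input file."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the Gaussian-mixture point cloud.

    Defaults describe the desk-scale stand-in for a conformational image
    dataset: ten mixture components (conformations) in 64 dimensions,
    unit within-cluster noise, and centroids whose typical pairwise
    Euclidean distance equals ``component_separation``.
    """

    N: int = 2000
    d: int = 64
    n_components: int = 10
    component_separation: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N, self.d, self.n_components) < 1:
            raise ValueError("N, d and n_components must all be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_synthetic(spec: SyntheticSpec) -> tuple[DataMatrix, np.ndarray]:
    """Draw the mixture cloud; a pure function of the spec.

    Component means are i.i.d. Gaussian with scale
    ``component_separation / sqrt(2 d)``, so the expected distance
    between two means is ~``component_separation``; points add isotropic
    noise of ``noise_sd`` per dimension.  Returns the d x N matrix and
    the length-N ground-truth component labels.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.component_separation / np.sqrt(2.0 * spec.d)
    means = scale * rng.standard_normal((spec.d, spec.n_components))
    labels = rng.integers(0, spec.n_components, size=spec.N)
    values = means[:, labels] + spec.noise_sd * rng.standard_normal(
        (spec.d, spec.N))
    return DataMatrix(values), labels


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".txt", ".csv", ".tsv", ".dat"):
        return "text"
    if suffix in (".bknn", ".bin"):
        return "binary"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise FormatError(
        f"cannot infer format from suffix {suffix!r}; pass format= explicitly"
    )


def read_matrix(path, format: str | None = None, *,
                skip_header: bool = False) -> DataMatrix:
    """Read a vector cloud from text, the binary container, or HDF5.

    Text files hold one vector per line; ragged lines are reported with
    their line number.  The result is the column-per-vector matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "text":
        return _read_text(path, skip_header)
    if fmt == "binary":
        return _read_binary(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "vectors" not in f:
                raise FormatError(f"{path}: missing 'vectors' dataset")
            return DataMatrix(np.asarray(f["vectors"]).T)
    raise FormatError(f"unknown matrix format {fmt!r}")


def _read_text(path: Path, skip_header: bool) -> DataMatrix:
    rows: list[np.ndarray] = []
    width = None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            if skip_header and lineno == 1:
                continue
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                row = np.array([float(x) for x in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if width is None:
                width = row.size
            elif row.size != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row of {row.size} values, "
                    f"expected {width}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return DataMatrix(np.vstack(rows).T)


def _read_binary(path: Path) -> DataMatrix:
    with open(path, "rb") as f:
        magic = f.read(len(_MAGIC))
        if magic != _MAGIC:
            raise FormatError(f"{path}: unknown magic {magic!r}")
        code, = struct.unpack("<B", f.read(1))
        if code not in _DTYPE_CODES:
            raise FormatError(f"{path}: unknown dtype code {code}")
        d, N = struct.unpack("<qq", f.read(16))
        if d < 1 or N < 1:
            raise FormatError(f"{path}: bad header d={d}, N={N}")
        dtype = _DTYPE_CODES[code]
        payload = np.fromfile(f, dtype=dtype, count=d * N)
        if payload.size != d * N:
            raise FormatError(f"{path}: truncated payload")
    return DataMatrix(payload.reshape((d, N), order="F"))


def write_matrix(X: DataMatrix, path, format: str | None = None) -> None:
    """Write a cloud in the format inferred from the suffix (or given)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "text":
        with open(path, "w") as f:
            for j in range(X.N):
                f.write(" ".join(f"{v:.17g}" for v in X.values[:, j]) + "\n")
    elif fmt == "binary":
        code = 1 if X.values.dtype == np.float32 else 0
        with open(path, "wb") as f:
            f.write(_MAGIC)
            f.write(struct.pack("<B", code))
            f.write(struct.pack("<qq", X.d, X.N))
            np.asfortranarray(X.values).ravel(order="F").tofile(f)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=X.values.T)
    else:
        raise FormatError(f"unknown matrix format {fmt!r}")


def write_knng(graph: KNNGraph, path, format: str = "edges") -> None:
    """Write a k-NN graph as a TSV edge list or a MatrixMarket file."""
    path = Path(path)
    if format == "edges":
        with open(path, "w") as f:
            f.write("# query\trank\tneighbor\tdistance\n")
            f.write(f"# N={graph.N} k={graph.k} metric={graph.metric} "
                    f"self_excluded={int(graph.self_excluded)}\n")
            for q in range(graph.N):
                for rank in range(graph.k):
                    f.write(f"{q}\t{rank + 1}\t{graph.neighbor_ids[q, rank]}\t"
                            f"{graph.distances[q, rank]:.17g}\n")
    elif format == "mtx":
        rows = np.repeat(np.arange(graph.N), graph.k)
        coo = scipy.sparse.coo_matrix(
            (graph.distances.ravel(), (rows, graph.neighbor_ids.ravel())),
            shape=(graph.N, graph.N),
        )
        scipy.io.mmwrite(str(path), coo)
    else:
        raise FormatError(f"unknown graph format {format!r}")


def read_knng(path) -> KNNGraph:
    """Read back a TSV edge-list graph written by :func:`write_knng`."""
    path = Path(path)
    meta: dict[str, str] = {}
    edges: list[tuple[int, int, int, float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                for tok in stripped.lstrip("#").split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        meta[key] = val
                continue
            parts = stripped.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            q, rank, nid = int(parts[0]), int(parts[1]), int(parts[2])
            edges.append((q, rank, nid, float(parts[3])))
    if not edges:
        raise FormatError(f"{path}: no edges")
    N = int(meta.get("N", max(e[0] for e in edges) + 1))
    k = int(meta.get("k", max(e[1] for e in edges)))
    ids = np.full((N, k), -1, dtype=np.int64)
    dists = np.full((N, k), np.nan)
    for q, rank, nid, dist in edges:
        ids[q, rank - 1] = nid
        dists[q, rank - 1] = dist
    if (ids < 0).any():
        raise FormatError(f"{path}: missing (query, rank) entries")
    return KNNGraph(N=N, k=k, neighbor_ids=ids, distances=dists,
                    metric=meta.get("metric", "euclidean"),
                    self_excluded=bool(int(meta.get("self_excluded", "1"))))
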