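"""Internal helpers: skeleton pixel graphs, geodesic paths, polyline length.

A skeleton is treated as a graph whose nodes are its pixels and whose
edges join 8-neighbours with weight 1 (edge neighbours) or sqrt(2)
(diagonal neighbours).  Geodesic path lengths reported to callers are
measured on the traced pixel path resampled every ``RESAMPLE_STEP``
pixels and summed as Euclidean segments: the raw chain length of an
8-connected digital line overestimates its true length by up to 8%
at worst-case orientation, while the resampled polyline is accurate to
well under 1% for paths whose curvature radius exceeds a few pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

RESAMPLE_STEP = 5

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def skeleton_graph(skel: np.ndarray) -> tuple[np.ndarray, csr_matrix]:
    """Build the weighted adjacency graph of a boolean skeleton raster.

    Returns (coords, graph) where coords is (n, 2) int and graph is a
    symmetric CSR matrix of chain-step weights.
    """
    coords = np.argwhere(skel)
    n = len(coords)
    index = np.full(skel.shape, -1, dtype=np.int64)
    index[coords[:, 0], coords[:, 1]] = np.arange(n)
    rows, cols, weights = [], [], []
    nrows, ncols = skel.shape
    for dr, dc in _NEIGHBOR_OFFSETS:
        r = coords[:, 0] + dr
        c = coords[:, 1] + dc
        ok = (r >= 0) & (r < nrows) & (c >= 0) & (c < ncols)
        src = np.flatnonzero(ok)
        dst = index[r[ok], c[ok]]
        hit = dst >= 0
        rows.append(src[hit])
        cols.append(dst[hit])
        w = np.sqrt(2.0) if dr and dc else 1.0
        weights.append(np.full(hit.sum(), w))
    graph = csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return coords, graph


def geodesic_farthest(graph: csr_matrix, source: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Dijkstra from ``source``; returns (farthest reachable node, dist, pred)."""
    dist, pred = dijkstra(graph, indices=source, return_predecessors=True)
    dist = np.where(np.isinf(dist), -1.0, dist)
    far = int(np.argmax(dist))
    return far, dist, pred


def extract_path(pred: np.ndarray, target: int) -> np.ndarray:
    """Node index sequence from the dijkstra source to ``target``."""
    path = [target]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return np.asarray(path[::-1])


def longest_geodesic(coords: np.ndarray, graph: csr_matrix, anchor: int | None = None):
    """Longest geodesic path in a skeleton component.

    With ``anchor`` given, the path starts there and runs to the farthest
    reachable pixel.  Without it, a double-sweep (farthest-from-farthest)
    approximates the component diameter, exact on tree-shaped skeletons.
    Returns (path_coords, chain_length_px).
    """
    if anchor is None:
        far0, _, _ = geodesic_farthest(graph, 0)
        anchor = far0
    far, dist, pred = geodesic_farthest(graph, anchor)
    path = extract_path(pred, far)
    return coords[path], float(dist[far])


def polyline_length(points: np.ndarray, step: int = RESAMPLE_STEP) -> float:
    """Euclidean length of a pixel path resampled every ``step`` vertices."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    idx = list(range(0, len(points), step))
    if idx[-1] != len(points) - 1:
        idx.append(len(points) - 1)
    sub = points[idx]
    return float(np.sqrt(((np.diff(sub, axis=0)) ** 2).sum(axis=1)).sum())
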