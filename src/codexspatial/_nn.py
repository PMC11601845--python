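"""Exact k-nearest-neighbour search with deterministic tie-breaking.

KD-tree libraries return ties in an unspecified order; every graph built in
this package must be reproducible bit-for-bit, so neighbours are ranked by
(distance, point index) with a chunked brute-force scan.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def exact_knn(points: np.ndarray, k: int, chunk_size: int = 512):
    """Return (indices, distances) of the k nearest neighbours of each point.

    Self-matches are excluded. Ties in distance are broken by the smaller
    point index, making the result independent of library internals.

    Parameters
    ----------
    points : (n, d) float array
    k : number of neighbours, must satisfy 1 <= k < n
    chunk_size : rows processed per distance block (memory knob only)

    Returns
    -------
    idx : (n, k) int array, idx[i] sorted by increasing distance to point i
    dist : (n, k) float array of the matching Euclidean distances
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, n-1]; got k={k} for n={n} points")
    idx = np.empty((n, k), dtype=np.intp)
    dist = np.empty((n, k), dtype=float)
    col = np.arange(n)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        d = cdist(pts[start:stop], pts)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        keys = np.broadcast_to(col, d.shape)
        order = np.lexsort((keys, d), axis=-1)[:, :k]
        idx[start:stop] = order
        dist[start:stop] = np.take_along_axis(d, order, axis=-1)
    return idx, dist
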