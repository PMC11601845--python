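"""Spatial kNN graphs and cellular-neighbourhood (CN) discovery.

A cellular neighbourhood is a recurring local composition motif: each cell
is summarised by the phenotype proportions among its k nearest spatial
neighbours (k = 10 by default, within the same ROI), and k-means clustering
of these composition vectors — with the number of clusters chosen by the
mean silhouette score — yields the CN labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._nn import exact_knn

__all__ = [
    "SpatialGraph",
    "NeighborhoodModel",
    "build_knn_graph",
    "neighbor_composition",
    "discover_neighborhoods",
    "cn_roi_proportions",
]


@dataclass
class SpatialGraph:
    """Per-ROI directed k-nearest-neighbour relation over cell centroids.

    `neighbor_idx[i]` holds the positions (into `cell_ids`) of cell i's k
    nearest neighbours in its own ROI, ordered by increasing distance
    (microns); `neighbor_dist` holds the matching distances.
    """

    cell_ids: np.ndarray
    roi: np.ndarray
    neighbor_idx: np.ndarray  # (n, k) positional indices
    neighbor_dist: np.ndarray  # (n, k) microns
    k: int

    def edge_list(self):
        """Directed edges as (source_pos, target_pos, distance) arrays."""
        n = self.cell_ids.shape[0]
        src = np.repeat(np.arange(n), self.k)
        return src, self.neighbor_idx.ravel(), self.neighbor_dist.ravel()


def build_knn_graph(cells: pd.DataFrame, k: int = 10) -> SpatialGraph:
    """Exact spatial kNN lists per ROI (Euclidean on centroids, microns).

    `cells` needs columns cell_id, roi_id, x_um, y_um. Edges never cross
    ROI boundaries, no cell is its own neighbour, and distance ties are
    broken by cell index so the graph is deterministic.

    Raises
    ------
    ValueError naming the ROI if any ROI has fewer than k + 1 cells.
    """
    for col in ("cell_id", "roi_id", "x_um", "y_um"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    n = len(cells)
    neighbor_idx = np.empty((n, k), dtype=np.intp)
    neighbor_dist = np.empty((n, k), dtype=float)
    pos = np.arange(n)
    roi = cells["roi_id"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    for r in pd.unique(roi):
        sel = pos[roi == r]
        if sel.shape[0] <= k:
            raise ValueError(f"ROI {r!r} has {sel.shape[0]} cells; need more than k={k}")
        idx, dist = exact_knn(xy[sel], k)
        neighbor_idx[sel] = sel[idx]
        neighbor_dist[sel] = dist
    return SpatialGraph(cell_ids=cells["cell_id"].to_numpy(), roi=roi,
                        neighbor_idx=neighbor_idx, neighbor_dist=neighbor_dist, k=k)


def neighbor_composition(graph: SpatialGraph, phenotypes: pd.Series,
                         include_self: bool = False) -> pd.DataFrame:
    """Cells-by-phenotypes matrix of neighbour-type proportions.

    Row i counts each phenotype among cell i's k neighbours and divides by
    the neighbour count, so rows sum to one. The index cell is excluded by
    default (it contributes its own label when ``include_self=True``, with
    the denominator k + 1).

    `phenotypes` must be indexed by cell_id and cover every cell in the
    graph.
    """
    ids = pd.Index(graph.cell_ids)
    missing = ids.difference(phenotypes.index)
    if len(missing):
        raise ValueError(f"phenotype missing for {len(missing)} cell(s), "
                         f"e.g. {list(missing[:3])}")
    lab = phenotypes.reindex(ids)
    if lab.isna().any():
        raise ValueError("phenotype labels contain missing values")
    cats = pd.Index(sorted(lab.unique()))
    codes = cats.get_indexer(lab)
    n, k = graph.neighbor_idx.shape
    counts = np.zeros((n, len(cats)), dtype=float)
    rows = np.repeat(np.arange(n), k)
    np.add.at(counts, (rows, codes[graph.neighbor_idx.ravel()]), 1.0)
    denom = k
    if include_self:
        counts[np.arange(n), codes] += 1.0
        denom = k + 1
    comp = pd.DataFrame(counts / denom, index=pd.Index(graph.cell_ids, name="cell_id"),
                        columns=cats)
    comp.attrs["roi_id"] = graph.roi
    return comp


@dataclass
class NeighborhoodModel:
    """k-means CN model plus the silhouette trace that selected its k."""

    k_cn: int
    centroids: pd.DataFrame  # k_cn x phenotypes, columns as in the composition matrix
    silhouette: dict  # candidate k -> mean silhouette score
    labels: pd.Series  # per-cell CN label (index cell_id)
    seed: int
    n_restarts: int


def discover_neighborhoods(comp: pd.DataFrame, k_candidates=range(2, 11),
                           seed: int = 0, n_restarts: int = 10,
                           silhouette_sample: int | None = 5000) -> NeighborhoodModel:
    """Cluster composition vectors into CNs, choosing k by mean silhouette.

    For every candidate k a k-means model is fitted (`n_restarts` seeded
    initialisations, best inertia kept) and the mean silhouette score is
    computed on a seeded random subsample of at most `silhouette_sample`
    rows (None = all rows). The model with the highest silhouette wins;
    ties go to the smaller k. Candidates exceeding the number of distinct
    rows are skipped with a warning, never silently chosen.

    Raises
    ------
    ValueError if no candidate k is feasible (e.g. all rows identical).
    """
    X = comp.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    candidates = [int(k) for k in k_candidates]
    if not candidates or min(candidates) < 2:
        raise ValueError("k candidates must be integers >= 2")
    feasible = []
    for k in candidates:
        if k > n_distinct:
            warnings.warn(f"skipping k={k}: only {n_distinct} distinct composition rows",
                          stacklevel=2)
        else:
            feasible.append(k)
    if not feasible:
        raise ValueError(
            f"no feasible number of neighbourhoods: {n_distinct} distinct composition "
            "row(s) cannot support any candidate k (degenerate input)")

    trace, models = {}, {}
    sample = None if silhouette_sample is None else min(silhouette_sample, X.shape[0])
    for k in feasible:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        trace[k] = float(silhouette_score(X, km.labels_, sample_size=sample,
                                          random_state=seed))
        models[k] = km
    best_k = max(sorted(trace), key=lambda k: trace[k])
    km = models[best_k]
    labels = pd.Series(km.labels_.astype(int), index=comp.index, name="cn")
    centroids = pd.DataFrame(km.cluster_centers_, columns=comp.columns)
    centroids.index.name = "cn"
    return NeighborhoodModel(k_cn=best_k, centroids=centroids, silhouette=trace,
                             labels=labels, seed=seed, n_restarts=n_restarts)


def cn_roi_proportions(labels: pd.Series, cells: pd.DataFrame) -> pd.DataFrame:
    """ROI-by-CN table of the proportion of each ROI's cells in each CN.

    Every observed CN appears as a column (zeros where absent); each row
    sums to one.
    """
    if "cell_id" not in cells.columns or "roi_id" not in cells.columns:
        raise ValueError("cell table lacks cell_id/roi_id columns")
    lab = labels.reindex(cells["cell_id"])
    if lab.isna().any():
        raise ValueError("every cell needs a CN label")
    tab = pd.crosstab(cells["roi_id"].to_numpy(), lab.to_numpy())
    tab = tab.div(tab.sum(axis=1), axis=0)
    tab.index.name = "roi_id"
    tab.columns.name = "cn"
    return tab
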