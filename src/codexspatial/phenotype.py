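"""Marker normalization and graph-based cell phenotyping.

Raw per-cell fluorescence intensities are variance-stabilised with an
inverse hyperbolic sine transform applied per marker within each ROI (which
also absorbs ROI-level batch effects), then z-scaled. Cells are embedded
with PCA, linked in an unweighted symmetrized k-nearest-neighbour graph in
PC space, and partitioned with the Leiden community-detection algorithm.
Cluster identities are assigned afterwards from average marker profiles.

The phrase "z-scaled across both cells and markers" admits two readings;
the default here standardises per marker across cells (within ROI) and then
per cell across markers, and ``scale="per-marker"`` keeps only the first
stage. Leiden is run on the modularity objective (RBConfiguration at the
requested resolution), configurable to CPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._nn import exact_knn

__all__ = [
    "NormalizedMatrix",
    "PhenotypeResult",
    "normalize",
    "cluster_cells",
    "profile_clusters",
    "annotate",
    "top_marker_mapping",
]


@dataclass
class NormalizedMatrix:
    """Normalized cells-by-markers matrix plus its provenance."""

    values: pd.DataFrame  # index cell_id, columns markers
    roi: pd.Series  # roi_id per cell, aligned with values
    cofactor: float
    scale: str
    dropped_markers: tuple = ()


@dataclass
class PhenotypeResult:
    """Leiden partition of cells with full parameter provenance."""

    labels: pd.Series  # index cell_id, values small ints
    n_pcs: int | None
    graph_k: int
    resolution: float
    seed: int
    objective: str = "modularity"
    cofactor: float | None = None
    scale: str | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _marker_columns(table: pd.DataFrame) -> list[str]:
    meta = {"cell_id", "roi_id", "cohort", "x_um", "y_um"}
    return [c for c in table.columns if c not in meta]


def normalize(marker_table: pd.DataFrame, cofactor: float = 1.0,
              scale: str = "both", on_constant: str = "raise") -> NormalizedMatrix:
    """asinh-transform and z-scale a raw marker-intensity table.

    Parameters
    ----------
    marker_table : DataFrame with `cell_id` and `roi_id` columns followed by
        one non-negative intensity column per marker.
    cofactor : asinh cofactor; intensities are mapped x -> asinh(x/cofactor)
        per marker within each ROI before scaling. Default 1 (bare asinh).
    scale : "both" (per-marker z within ROI, then per-cell z across markers)
        or "per-marker" (first stage only).
    on_constant : what to do with a marker that is constant within some ROI
        (cannot be z-scaled): "raise" (default) or "drop" it globally with
        a warning.

    Raises
    ------
    ValueError on missing/NaN/negative intensities, duplicate cell ids, or
    constant markers under ``on_constant="raise"`` (the error names them).
    """
    if scale not in ("both", "per-marker"):
        raise ValueError(f"scale must be 'both' or 'per-marker', got {scale!r}")
    if on_constant not in ("raise", "drop"):
        raise ValueError(f"on_constant must be 'raise' or 'drop', got {on_constant!r}")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    for col in ("cell_id", "roi_id"):
        if col not in marker_table.columns:
            raise ValueError(f"marker table lacks required column {col!r}")
    if marker_table["cell_id"].duplicated().any():
        dup = marker_table.loc[marker_table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in marker table (e.g. {dup!r})")
    markers = _marker_columns(marker_table)
    if not markers:
        raise ValueError("marker table has no marker columns")
    X = marker_table[markers].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("marker intensities must be finite with no missing values")
    if (X < 0).any():
        raise ValueError("marker intensities must be non-negative")

    roi = marker_table["roi_id"].to_numpy()
    T = np.arcsinh(X / cofactor)

    constant = []  # (marker, roi) pairs that cannot be scaled
    for r in pd.unique(roi):
        sel = roi == r
        spread = T[sel].max(axis=0) - T[sel].min(axis=0)
        for j in np.flatnonzero(spread == 0):
            constant.append((markers[j], r))
    drop_markers = sorted({m for m, _ in constant})
    if constant and on_constant == "raise":
        details = ", ".join(f"{m!r} in {r!r}" for m, r in constant[:5])
        raise ValueError(f"zero-variance marker(s) cannot be z-scaled: {details}")
    if drop_markers:
        warnings.warn(f"dropping constant marker(s): {drop_markers}", stacklevel=2)
        keep = [j for j, m in enumerate(markers) if m not in drop_markers]
        if not keep:
            raise ValueError("all markers are constant; nothing to normalize")
        T = T[:, keep]
        markers = [markers[j] for j in keep]

    Z = np.empty_like(T)
    for r in pd.unique(roi):
        sel = roi == r
        mu = T[sel].mean(axis=0)
        sd = T[sel].std(axis=0)
        Z[sel] = (T[sel] - mu) / sd
    if scale == "both":
        row_mu = Z.mean(axis=1, keepdims=True)
        row_sd = Z.std(axis=1, keepdims=True)
        flat = row_sd[:, 0] == 0
        if flat.any():
            warnings.warn(f"{int(flat.sum())} cell(s) had identical values across all "
                          "markers after per-marker scaling; set to 0", stacklevel=2)
            row_sd[flat] = 1.0
        Z = (Z - row_mu) / row_sd

    values = pd.DataFrame(Z, index=pd.Index(marker_table["cell_id"], name="cell_id"),
                          columns=markers)
    roi_s = pd.Series(roi, index=values.index, name="roi_id")
    return NormalizedMatrix(values=values, roi=roi_s, cofactor=cofactor,
                            scale=scale, dropped_markers=tuple(drop_markers))


_OBJECTIVES = {
    "modularity": la.RBConfigurationVertexPartition,
    "cpm": la.CPMVertexPartition,
}


def cluster_cells(matrix, n_pcs: int | None = 20, graph_k: int = 30,
                  resolution: float = 1.0, seed: int = 0,
                  objective: str = "modularity") -> PhenotypeResult:
    """Partition cells into phenotype clusters.

    PCA to `n_pcs` components (capped at the matrix rank bounds; pass None
    to skip PCA entirely), exact kNN graph in PC space (k = `graph_k`, self
    excluded, edges symmetrized by union, unweighted, distance ties broken
    by cell index), then Leiden at the given resolution. Deterministic for
    a fixed seed.
    """
    if isinstance(matrix, NormalizedMatrix):
        values, cofactor, scale = matrix.values, matrix.cofactor, matrix.scale
    else:
        values, cofactor, scale = matrix, None, None
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {sorted(_OBJECTIVES)}, got {objective!r}")
    X = values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < graph_k + 1:
        raise ValueError(f"need at least graph_k+1={graph_k + 1} cells, got {n}")
    if n_pcs is not None:
        ncomp = min(n_pcs, X.shape[1], n)
        pcs = PCA(n_components=ncomp, svd_solver="full").fit_transform(X)
    else:
        ncomp = None
        pcs = X

    idx, _ = exact_knn(pcs, graph_k)
    src = np.repeat(np.arange(n), graph_k)
    dst = idx.ravel()
    und = np.unique(np.stack([np.minimum(src, dst), np.maximum(src, dst)], axis=1), axis=0)
    graph = ig.Graph(n=n, edges=und.tolist())
    part = la.find_partition(graph, _OBJECTIVES[objective],
                             resolution_parameter=resolution, seed=seed)
    labels = pd.Series(part.membership, index=values.index, name="cluster", dtype=int)
    return PhenotypeResult(labels=labels, n_pcs=ncomp, graph_k=graph_k,
                           resolution=resolution, seed=seed, objective=objective,
                           cofactor=cofactor, scale=scale)


def profile_clusters(result: PhenotypeResult, matrix) -> pd.DataFrame:
    """Cluster-by-marker table of mean normalized expression.

    Row c is the arithmetic mean profile of the cells with cluster label c;
    this is the table one inspects (usually as a heatmap) to annotate
    clusters with cell-type names.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if not result.labels.index.equals(values.index):
        raise ValueError("cluster labels and matrix rows are not aligned")
    prof = values.groupby(result.labels).mean()
    prof.index.name = "cluster"
    return prof.sort_index()


def annotate(result: PhenotypeResult, mapping: Mapping[int, str]) -> pd.Series:
    """Map cluster labels to phenotype names (user- or profile-supplied).

    Every cluster label must be covered; uncovered labels raise with the
    full list so partial annotation never passes silently.
    """
    present = sorted(result.labels.unique())
    missing = [c for c in present if c not in mapping]
    if missing:
        raise ValueError(f"annotation mapping does not cover cluster label(s): {missing}")
    return result.labels.map(mapping).rename("phenotype")


def top_marker_mapping(profiles: pd.DataFrame,
                       marker_to_phenotype: Mapping[str, str] | None = None) -> dict:
    """Annotate each cluster by its highest-mean marker.

    A convenience for canonical-marker panels where each phenotype has one
    defining marker: cluster -> argmax marker of its mean profile, optionally
    translated through `marker_to_phenotype`. Mirrors the manual step of
    reading a cluster-profile heatmap.
    """
    top = profiles.idxmax(axis=1)
    if marker_to_phenotype is not None:
        top = top.map(lambda m: marker_to_phenotype.get(m, m))
    return dict(top)
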