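"""Spatial statistics: minimal inter-type distances, cohort comparisons and
cell-cell interaction enrichment.

The average minimum distance from type A to type B in an ROI is the mean,
over cells i of type A, of the distance from i to its nearest cell of type
B. Note the metric is directional (mean of minima): A->B generally differs
from B->A. Cohort contrasts use Welch's unequal-variance t-test; CN
proportion contrasts are variance-stabilised (asinh by default, atanh
optionally) and Bonferroni-corrected across CNs.

The interaction analysis is a permutation enrichment on the fixed spatial
graph: the observed count of directed edges joining an ordered phenotype
pair (restricted to a distance band, 3-100 um by default) is compared with
its distribution under random reassignment of phenotype labels within each
ROI. The published analysis states only the graph (k = 10) and the band;
the permutation design here is this package's declared re-implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .neighborhoods import SpatialGraph

__all__ = [
    "ComparisonResult",
    "min_distance",
    "compare_distance",
    "compare_cn_proportions",
    "interaction_enrichment",
]


@dataclass
class ComparisonResult:
    """A single statistical contrast with its provenance."""

    contrast: str
    statistic: float
    p_raw: float
    df: float | tuple | None = None
    p_adj: float | None = None
    adjust_method: str | None = None
    method: str = ""
    group_summaries: dict = field(default_factory=dict)  # group -> (n, mean, sd)


def _phen_series(phenotypes: pd.Series, cell_ids: np.ndarray) -> np.ndarray:
    lab = phenotypes.reindex(pd.Index(cell_ids))
    if lab.isna().any():
        raise ValueError("phenotype label missing for some cells")
    return lab.to_numpy()


def min_distance(cells: pd.DataFrame, phenotypes: pd.Series,
                 type_a: str, type_b: str) -> pd.DataFrame:
    """Per-ROI average minimum distance from `type_a` cells to `type_b` cells.

    For each cell of type A the distance to its nearest type-B cell is
    taken (self excluded when A == B), and the per-ROI mean of these minima
    is reported in microns. ROIs where either type is absent (or where
    A == B with fewer than two cells) yield NaN with the source count
    recorded — flagged missing, never silently zero.

    Returns a DataFrame [roi_id, type_a, type_b, mean_min_dist, n_source].
    """
    from scipy.spatial import cKDTree

    lab = _phen_series(phenotypes, cells["cell_id"].to_numpy())
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    roi = cells["roi_id"].to_numpy()
    rows = []
    for r in pd.unique(roi):
        sel = roi == r
        a_pts = xy[sel & (lab == type_a)]
        b_pts = xy[sel & (lab == type_b)]
        n_a, n_b = a_pts.shape[0], b_pts.shape[0]
        value = np.nan
        if type_a == type_b:
            if n_a >= 2:
                d, _ = cKDTree(a_pts).query(a_pts, k=2)
                value = float(d[:, 1].mean())
        elif n_a >= 1 and n_b >= 1:
            d, _ = cKDTree(b_pts).query(a_pts, k=1)
            value = float(np.asarray(d).mean())
        rows.append({"roi_id": r, "type_a": type_a, "type_b": type_b,
                     "mean_min_dist": value, "n_source": n_a})
    return pd.DataFrame(rows)


def compare_distance(distances: pd.DataFrame,
                     cohorts: Mapping[str, str] | pd.Series) -> ComparisonResult:
    """Welch two-sample t-test on per-ROI average minimum distances.

    `cohorts` maps roi_id to exactly one of two cohort labels. ROIs with a
    flagged-missing distance are dropped; each cohort must retain at least
    two usable ROIs.
    """
    cohorts = pd.Series(dict(cohorts)) if not isinstance(cohorts, pd.Series) else cohorts
    df = distances.dropna(subset=["mean_min_dist"]).copy()
    df["cohort"] = df["roi_id"].map(cohorts)
    if df["cohort"].isna().any():
        missing = df.loc[df["cohort"].isna(), "roi_id"].tolist()
        raise ValueError(f"no cohort assigned for ROI(s): {missing}")
    groups = {c: g["mean_min_dist"].to_numpy() for c, g in df.groupby("cohort")}
    if len(groups) != 2:
        raise ValueError(f"exactly two cohorts required, got {sorted(groups)}")
    for c, v in groups.items():
        if v.shape[0] < 2:
            raise ValueError(f"cohort {c!r} has {v.shape[0]} usable ROI(s); need >= 2")
    (ca, va), (cb, vb) = sorted(groups.items())
    res = sps.ttest_ind(va, vb, equal_var=False)
    summaries = {c: (int(v.shape[0]), float(v.mean()), float(v.std(ddof=1)))
                 for c, v in groups.items()}
    pair = distances["type_a"].iloc[0], distances["type_b"].iloc[0]
    return ComparisonResult(
        contrast=f"mean_min_dist[{pair[0]}->{pair[1]}]: {ca} vs {cb}",
        statistic=float(res.statistic), p_raw=float(res.pvalue), df=float(res.df),
        method="welch_t", group_summaries=summaries)


def compare_cn_proportions(props: pd.DataFrame, cohorts: Mapping[str, str] | pd.Series,
                           transform: str = "asinh") -> pd.DataFrame:
    """Per-CN cohort comparison of transformed ROI proportions.

    Each CN column of the ROI-by-CN proportion table is transformed (asinh,
    or atanh with clamping at 1 - 1e-9), Welch-tested between the two
    cohorts, and Bonferroni-corrected over the number of CN columns. CNs
    with degenerate data (zero variance in both cohorts) are flagged with
    NaN statistics but still count in the correction denominator.

    Returns a tidy DataFrame, one row per CN.
    """
    if transform not in ("asinh", "atanh"):
        raise ValueError(f"transform must be 'asinh' or 'atanh', got {transform!r}")
    cohorts = pd.Series(dict(cohorts)) if not isinstance(cohorts, pd.Series) else cohorts
    assign = cohorts.reindex(props.index)
    if assign.isna().any():
        raise ValueError(f"ROI(s) without cohort: {list(props.index[assign.isna()])}")
    names = sorted(assign.unique())
    if len(names) != 2:
        raise ValueError(f"exactly two cohorts required, got {names}")
    vals = props.to_numpy(dtype=float)
    if transform == "asinh":
        tv = np.arcsinh(vals)
    else:
        tv = np.arctanh(np.clip(vals, None, 1 - 1e-9))
    m = props.shape[1]
    a_mask = (assign == names[0]).to_numpy()
    rows = []
    for j, cn in enumerate(props.columns):
        va, vb = tv[a_mask, j], tv[~a_mask, j]
        degenerate = va.std() == 0 and vb.std() == 0
        if degenerate:
            t = p = np.nan
        else:
            res = sps.ttest_ind(va, vb, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "cn": cn, "statistic": t, "p_raw": p,
            "p_bonferroni": min(1.0, m * p) if np.isfinite(p) else np.nan,
            "mean_" + str(names[0]): float(va.mean()),
            "mean_" + str(names[1]): float(vb.mean()),
            "n_" + str(names[0]): int(va.shape[0]),
            "n_" + str(names[1]): int(vb.shape[0]),
            "degenerate": bool(degenerate),
            "transform": transform,
        })
    return pd.DataFrame(rows)


def interaction_enrichment(graph: SpatialGraph, phenotypes: pd.Series,
                           n_perm: int = 1000, seed: int = 0,
                           band=(3.0, 100.0)) -> pd.DataFrame:
    """Permutation enrichment of ordered phenotype pairs on the spatial graph.

    Directed edges with length inside `band` (microns, inclusive) are
    counted per ordered phenotype pair; the null distribution shuffles
    phenotype labels within each ROI while keeping the graph fixed. The
    z-score is (observed - null mean) / null sd (NaN when the null is
    degenerate) and the empirical two-sided p-value uses the add-one
    estimator, so it is never exactly zero.

    Returns a tidy DataFrame, one row per ordered pair of observed
    phenotypes.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    lo, hi = band
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid distance band {band}")
    lab = _phen_series(phenotypes, graph.cell_ids)
    cats = pd.Index(sorted(pd.unique(lab)))
    codes = cats.get_indexer(lab)
    t = len(cats)

    src, dst, dist = graph.edge_list()
    keep = (dist >= lo) & (dist <= hi)
    src, dst = src[keep], dst[keep]

    def pair_counts(c):
        return np.bincount(c[src] * t + c[dst], minlength=t * t).astype(float)

    observed = pair_counts(codes)
    rng = np.random.default_rng(seed)
    roi_groups = [np.flatnonzero(graph.roi == r) for r in pd.unique(graph.roi)]
    null = np.empty((n_perm, t * t))
    shuffled = codes.copy()
    for b in range(n_perm):
        for g in roi_groups:
            shuffled[g] = codes[g][rng.permutation(g.shape[0])]
        null[b] = pair_counts(shuffled)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    n_hi = (null >= observed).sum(axis=0)
    n_lo = (null <= observed).sum(axis=0)
    p_emp = np.minimum(1.0, (1.0 + 2.0 * np.minimum(n_hi, n_lo)) / (n_perm + 1.0))

    rows = []
    for i, a in enumerate(cats):
        for j, b_ in enumerate(cats):
            k = i * t + j
            rows.append({
                "type_a": a, "type_b": b_, "observed": int(observed[k]),
                "null_mean": null_mean[k], "null_sd": null_sd[k],
                "z": z[k], "p_emp": p_emp[k], "n_perm": n_perm,
                "band_min_um": lo, "band_max_um": hi,
                "degenerate": bool(null_sd[k] == 0),
            })
    return pd.DataFrame(rows)
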