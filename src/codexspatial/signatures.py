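"""Gene-set signature scoring and group-level statistics.

The combined z-score of a gene set (e.g. a 24-gene tertiary-lymphoid-
structure signature or an interferon-gamma response signature) is a
Stouffer-style statistic: each member gene is z-standardised across
samples and the per-sample sum of member z-scores is divided by the square
root of the number of member genes, which stabilises the variance of the
mean — for independent standard-normal member genes the combined score is
itself approximately standard normal. Samples are stratified into
high/low groups at the median score, and group effects are assessed with
Welch's t-test (two groups), Welch's ANOVA (three or more), Fisher's exact
test (count associations) and paired t-tests with Benjamini-Hochberg
correction (matched pre/post designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import ComparisonResult

__all__ = [
    "SignatureDefinition",
    "score_signature",
    "stratify_by_median",
    "group_tests",
    "fisher_association",
    "paired_comparison",
    "read_signatures_csv",
    "read_gmt",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named, ordered gene set. Symbols are matched case-sensitively."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no member genes")
        if len(set(self.genes)) != len(self.genes):
            dup = [g for g in self.genes if list(self.genes).count(g) > 1]
            raise ValueError(f"signature {self.name!r} has duplicate symbols: {sorted(set(dup))}")

    def __len__(self):
        return len(self.genes)


def score_signature(matrix: pd.DataFrame, sig: SignatureDefinition,
                    alias_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Combined z-score of a gene set, one score per sample.

    Each member gene present in the matrix is z-standardised across samples
    (sample sd, ddof 1) and the per-sample z's are summed and divided by
    sqrt(n genes used). Member genes absent from the matrix, or constant
    across samples, are excluded with a warning and n reduced accordingly —
    never imputed, so the sqrt-n scale claim stays valid.

    Parameters
    ----------
    matrix : samples x genes expression DataFrame (already normalized).
    sig : the gene set.
    alias_map : optional member-symbol -> matrix-column translation applied
        before exact matching.

    Returns a DataFrame [signature, score, n_genes_used] indexed by sample.
    """
    if matrix.shape[0] < 3:
        raise ValueError(f"need at least 3 samples to standardise genes, got {matrix.shape[0]}")
    wanted = [alias_map.get(g, g) if alias_map else g for g in sig.genes]
    present = [g for g in wanted if g in matrix.columns]
    absent = [g for g in wanted if g not in matrix.columns]
    if absent:
        warnings.warn(f"signature {sig.name!r}: {len(absent)} member gene(s) absent "
                      f"from the matrix: {absent[:5]}", stacklevel=2)
    if not present:
        raise ValueError(f"no member gene of signature {sig.name!r} is present in the matrix")
    sub = matrix[present].astype(float)
    sd = sub.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"signature {sig.name!r}: excluding zero-variance gene(s): "
                      f"{constant[:5]}", stacklevel=2)
        sub = sub.drop(columns=constant)
    if sub.shape[1] == 0:
        raise ValueError(f"signature {sig.name!r}: all present member genes are constant")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    n_used = z.shape[1]
    combined = z.sum(axis=1) / np.sqrt(n_used)
    return pd.DataFrame({"signature": sig.name, "score": combined,
                         "n_genes_used": n_used})


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """Median split into "high"/"low" strata (ties at the median go low).

    With distinct scores and even n the strata are exactly balanced; with
    odd n they differ by one (the median sample lands in the low stratum).
    """
    s = pd.Series(scores, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 samples to stratify")
    if s.nunique() == 1:
        raise ValueError("all scores identical; median stratification is undefined")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="stratum")


def group_tests(scores: pd.Series, groups: pd.Series) -> ComparisonResult:
    """Welch's t (2 groups) or Welch's ANOVA (>= 3 groups) on scores.

    Both tests drop the equal-variance assumption; the ANOVA uses the
    Welch (1951) F approximation as implemented in pingouin.
    """
    s = pd.Series(scores, dtype=float)
    g = pd.Series(groups).reindex(s.index)
    if g.isna().any():
        raise ValueError("every sample needs a group label")
    sizes = g.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton group(s) not testable: {small}")
    names = sorted(sizes.index)
    summaries = {k: (int(sizes[k]), float(s[g == k].mean()), float(s[g == k].std(ddof=1)))
                 for k in names}
    if len(names) == 2:
        res = sps.ttest_ind(s[g == names[0]], s[g == names[1]], equal_var=False)
        return ComparisonResult(contrast=f"{names[0]} vs {names[1]}",
                                statistic=float(res.statistic), p_raw=float(res.pvalue),
                                df=float(res.df), method="welch_t",
                                group_summaries=summaries)
    import pingouin as pg

    df = pd.DataFrame({"score": s, "group": g})
    aov = pg.welch_anova(data=df, dv="score", between="group")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return ComparisonResult(contrast=" vs ".join(map(str, names)),
                            statistic=float(aov["F"].iloc[0]),
                            p_raw=float(aov[p_col].iloc[0]),
                            df=(float(aov["ddof1"].iloc[0]), float(aov["ddof2"].iloc[0])),
                            method="welch_anova", group_summaries=summaries)


def fisher_association(table) -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {tab.shape}")
    if not np.issubdtype(tab.dtype, np.integer):
        if not np.allclose(tab, np.round(tab)):
            raise ValueError("table entries must be non-negative integers")
        tab = np.round(tab).astype(int)
    if (tab < 0).any():
        raise ValueError("table entries must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("both margins of the 2x2 table must be positive")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return ComparisonResult(contrast="2x2 association", statistic=float(odds),
                            p_raw=float(p), method="fisher_exact")


def _paired_t(pre: np.ndarray, post: np.ndarray):
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return np.inf * np.sign(diff.mean()), 0.0
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def paired_comparison(pre_scores: pd.Series, post_scores: pd.Series,
                      gene_level: tuple[pd.DataFrame, pd.DataFrame] | None = None):
    """Paired t-test of matched pre/post samples, optionally per gene.

    Samples are matched by index; any sample present on only one side is an
    orphan and raises (the error lists them). When `gene_level` supplies
    matched pre/post expression matrices, every shared gene gets a paired t
    with Benjamini-Hochberg step-up q-values across genes.

    Returns (ComparisonResult, per-gene DataFrame or None).
    """
    pre = pd.Series(pre_scores, dtype=float)
    post = pd.Series(post_scores, dtype=float)
    orphans = pre.index.symmetric_difference(post.index)
    if len(orphans):
        raise ValueError(f"unmatched sample(s): {sorted(map(str, orphans))}")
    if pre.shape[0] < 2:
        raise ValueError("need at least 2 matched pairs")
    post = post.reindex(pre.index)
    t, p = _paired_t(pre.to_numpy(), post.to_numpy())
    result = ComparisonResult(contrast="post vs pre (paired)", statistic=t, p_raw=p,
                              df=float(pre.shape[0] - 1), method="paired_t")
    gene_table = None
    if gene_level is not None:
        pre_m, post_m = gene_level
        if len(pre_m.index.symmetric_difference(post_m.index)):
            raise ValueError("gene-level matrices have unmatched samples")
        post_m = post_m.reindex(pre_m.index)
        genes = [g for g in pre_m.columns if g in post_m.columns]
        stats_, ps = [], []
        for gname in genes:
            tg, pg_ = _paired_t(pre_m[gname].to_numpy(dtype=float),
                                post_m[gname].to_numpy(dtype=float))
            stats_.append(tg)
            ps.append(pg_)
        ps = np.asarray(ps)
        valid = np.isfinite(ps)
        q = np.full_like(ps, np.nan)
        if valid.any():
            q[valid] = multipletests(ps[valid], method="fdr_bh")[1]
        gene_table = pd.DataFrame({"gene": genes, "statistic": stats_,
                                   "p_raw": ps, "q_bh": q})
    return result, gene_table


def read_signatures_csv(path) -> dict[str, SignatureDefinition]:
    """Read signatures from a two-column CSV (signature, gene)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "signature" not in cols or "gene" not in cols:
        raise ValueError("signature CSV needs columns 'signature' and 'gene'")
    df.columns = cols
    return {name: SignatureDefinition(name=name, genes=tuple(g["gene"]))
            for name, g in df.groupby("signature", sort=False)}


def read_gmt(path) -> dict[str, SignatureDefinition]:
    """Read signatures from a GMT file (name <tab> description <tab> genes...)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], tuple(g for g in parts[2:] if g)
            out[name] = SignatureDefinition(name=name, genes=genes)
    return out
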