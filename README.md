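# codexspatial

Spatial single-cell analysis of CODEX multiplexed-imaging data, with the
gene-signature statistics used alongside it in immunotherapy correlative
studies. The package is aimed at computational biologists analysing
multiplexed immunofluorescence of tumour tissue (the motivating setting is
metastatic clear-cell renal cell carcinoma under immune checkpoint therapy),
where the *spatial arrangement* of immune cells — not just their abundance —
separates responders from non-responders.

## What it computes

**Whole-cell mask dilation.** Nuclear segmentation masks are grown into
approximate whole-cell masks by a stochastic, diffusion-like rule: in each of
9 rounds, every background pixel adjacent to a mask joins it with probability
equal to the fraction of its neighbouring pixels already assigned to that
mask. The update is synchronous per round, with a documented RNG contract so
results are reproducible bit-for-bit.

**Phenotyping.** Per-cell marker intensities x are transformed
`x → asinh(x / c)` per marker within each ROI (cofactor c = 1 by default),
z-scaled, embedded with PCA (20 components), linked in an unweighted
symmetrised k-nearest-neighbour graph (k = 30) and partitioned with the
Leiden algorithm at resolution 1.0. Clusters are annotated to cell types from
their average marker profiles.

**Cellular neighbourhoods (CNs).** Each cell is summarised by the phenotype
proportions among its 10 nearest spatial neighbours (per ROI, in microns);
k-means on these composition vectors — with k chosen by maximising the mean
silhouette score over k = 2..10 — yields recurring local motifs such as
tumour cores or lymphoid aggregates.

**Spatial statistics.** The average minimum distance from type A to type B in
an ROI is `mean_i min_j d(a_i, b_j)` (directional by construction); cohorts
are compared with Welch's t-test. ROI-level CN proportions are
asinh-transformed, Welch-tested per CN and Bonferroni-corrected. Cell–cell
interaction enrichment is a permutation test on the fixed spatial graph
(phenotype labels shuffled within ROI; edges restricted to a 3–100 µm band),
reported as z-scores and add-one empirical p-values.

**Gene signatures.** A gene set (e.g. a 24-gene tertiary-lymphoid-structure
signature) is scored per sample by the combined z-score
`Z_s = Σ_g z_gs / √n`, the Stouffer-style statistic whose √n denominator
keeps the score's variance near 1. Samples are split at the median score;
groups are compared with Welch's t-test / Welch's ANOVA, count associations
with Fisher's exact test, and matched pre/post designs with paired t-tests
under Benjamini–Hochberg correction.

All inputs the pipeline needs can be generated by the built-in synthetic-data
module (planted spatial neighbourhoods, lognormal marker intensities,
non-overlapping nuclear masks, group-shifted expression matrices), each with
ground truth emitted alongside.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
import codexspatial as cx

cfg = cx.default_tissue_config(seed=0, n_rois=4, cells_per_roi=300)
cells, markers, truth = cx.simulate_tissue(cfg)

nm = cx.normalize(markers)                      # asinh + z-scaling
res = cx.cluster_cells(nm, seed=0)              # PCA-20, kNN-30, Leiden 1.0
prof = cx.profile_clusters(res, nm)
mapping = cx.top_marker_mapping(prof, {"PanCK": "Tumor", "CD8": "CD8T",
                                       "CD4": "CD4T", "CD20": "B",
                                       "CD11c": "DC", "CD68": "Macrophage"})
phen = cx.annotate(res, mapping)

print(res.n_clusters)
print(round(adjusted_rand_score(truth["true_type"], phen), 3))

d = cx.min_distance(cells, phen, "B", "CD8T")
print(d[["roi_id", "mean_min_dist"]].round(1).to_string(index=False))
```

prints

```
9
0.977
roi_id  mean_min_dist
ROI000           49.0
ROI001           61.3
ROI002           54.3
ROI003          144.2
```

Leiden at resolution 1.0 splits the six planted cell types into 9 raw
clusters; merging clusters by their top average marker recovers the planted
types almost perfectly (adjusted Rand index 0.977). The distance table gives,
per ROI, the mean distance (µm) from each B cell to its nearest CD8 T cell —
the quantity that is shorter in responder tissue, where B cells aggregate
with T cells. ROIs alternate cohorts here (ROI000/ROI002 responder,
ROI001/ROI003 non-responder), and the tumour-dominated non-responder ROIs
indeed show the larger B→CD8 distances.

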