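# Methods

This note documents the models, the defaults and the numerical conventions
behind `codexspatial`, and what the synthetic-data experiments do and do not
establish about real multiplexed-imaging data.

## Stochastic mask dilation

Nuclear masks underestimate cell area, so each mask is grown for `rounds`
(default 9) synchronous passes. In one pass, every background pixel with at
least one assigned neighbour ("border pixel") is considered: its candidate
mask is the one holding the most of its neighbours (ties to the smallest
label id), and it joins that mask with probability
`p = (candidate's neighbour count) / (in-bounds neighbour count)`. Because
probabilities are read from the start-of-pass state, growth has no
scan-order artefacts; because assigned pixels are immutable, masks remain
disjoint, the input is contained in the output, and no pixel ends farther
than `rounds` connectivity steps from its mask's original support.

Choices the underlying description leaves open, fixed here as conventions:

* **Connectivity** — 8-connected by default (denser, diffusion-like
  growth); 4-connected available. The reach bound uses the matching metric
  (chessboard / taxicab).
* **Contested pixels** — a pixel adjacent to several masks is claimed by
  the majority mask (ties to the smallest label) and decided by a single
  uniform draw; masks never compete stochastically for the same pixel
  within a round.
* **RNG contract** — border pixels are enumerated row-major and consume
  exactly one uniform each, drawn as one `Generator.random(n)` block per
  round. This makes the output bit-reproducible and lets a naive per-pixel
  reference replay the stream exactly (the equivalence is tested on 20
  seeded fixtures).

## Normalization and phenotyping

Raw intensities are `asinh(x / cofactor)`-transformed per marker within each
ROI (cofactor 1.0 by default, i.e. a bare asinh; fluorescence counts have no
natural scale here), which also absorbs ROI-level batch effects. "z-scaling
across cells and markers" is implemented as two sequential standardisations:
per marker across the cells of each ROI, then per cell across markers; the
`per-marker` mode keeps only the first stage. Markers constant within a
stratum cannot be z-scaled and either raise or are dropped explicitly.

Clustering is PCA (20 components, full SVD for determinism) followed by an
exact unweighted symmetrised kNN graph (k = 30; ties broken by cell index,
which is why the kNN search is a brute-force (distance, index) lexsort
rather than a KD-tree) and Leiden at resolution 1.0 under the modularity
objective (RBConfiguration; CPM available). Seeds fix the partition.

**A property users should expect:** modularity maximisation at resolution
1.0 splits large homogeneous groups. Three well-separated planted types of
~670 cells each yield ~9–19 Leiden clusters, every one of them >99% pure.
This mirrors practice on real tissue, where Leiden produces more clusters
than cell types (e.g. 15 clusters annotated down to ~8 types) and identities
are assigned by reading average-expression profiles. Recovery is therefore
assessed after the annotation step (`top_marker_mapping` maps each cluster
to its highest-mean canonical marker); the tests require >=95% cluster
purity and annotated ARI >= 0.95.

## Cellular neighbourhoods

The spatial graph links each cell to its 10 nearest neighbours within its
ROI (Euclidean on centroids in microns; index tie-break). The composition
matrix divides per-phenotype neighbour counts by k, excluding the index cell
by default (a configurable convention). CNs are k-means clusters of these
vectors; k-means runs 10 seeded restarts per candidate k in 2..10 and the
mean silhouette (Euclidean, on a seeded subsample of at most 5000 rows for
tractability) selects k, ties to the smaller k. Candidates exceeding the
number of distinct rows are skipped loudly; an all-identical matrix is a
hard error. Proportions (not counts) are clustered by default.

**Known limitation — silhouette on discrete compositions.** With k = 10
neighbours, composition vectors live on the lattice of multiples of 1/10.
If planted motifs have disjoint type support, most cells collapse onto a few
lattice points and the silhouette rewards splitting popular points into
zero-diameter singleton clusters, inflating the selected k. Real
neighbourhoods are never pure, so the planted-recovery study uses
full-support motifs (tumour-dominated / B–T lymphoid / DC–macrophage
myeloid); under those conditions (5000 cells, 2 ROIs of 1500 µm, 5 region
centres of radius 220 µm per ROI) silhouette selects k = 3 in >= 18 of 20
seeds with median ARI >= 0.9. Conversely, motifs whose composition profiles
overlap strongly (e.g. two lymphoid variants) merge: on the default
four-motif cohort the selected k is typically 2–3. Silhouette-selected
k-means finds strongly distinct motifs, not subtle ones.

## Spatial statistics

`min_distance` is the directional mean-of-minima in microns (self excluded
when A = B; absent types yield flagged NaN, never zero) and is checked
exactly against an O(n²) scan. Cohort contrasts use Welch's t with
Welch–Satterthwaite degrees of freedom. CN proportions are asinh-transformed
before testing — the variance-stabilising routine actually named in the
originating analysis; an atanh mode (clamped at 1 − 1e−9) is provided since
prose and routine name disagree — and Bonferroni-corrected with
`min(1, m·p)` over all m CN columns, degenerate columns included in m.

The interaction analysis is this package's own permutation design (the
originating description names only the k = 10 graph and a 3–100 µm range):
observed counts of directed edges per ordered phenotype pair inside the
band, nulls from shuffling labels within each ROI with the graph fixed,
z = (obs − mean)/sd (ddof 1; NaN when the null is degenerate) and add-one
two-sided empirical p in (0, 1]. Defaults: 1000 permutations, minimum 100.

## Gene signatures

Member genes are z-standardised across samples (ddof 1) and combined as
`Σ z / √n`; genes absent from the matrix or constant are excluded with a
warning and n reduced — never imputed — preserving the unit-variance claim
(verified: sd of the combined score over 2000 independent-normal samples
lies in [0.95, 1.05]). Symbol matching is case-sensitive with an explicit
alias-map hook. Median stratification sends ties at the median to "low"
(declared convention), so odd cohorts split (n+1)/2 low. Two-group contrasts
use Welch's t; three or more use Welch's ANOVA (pingouin); count
associations use the two-sided exact hypergeometric sum (checked against
exhaustive enumeration); paired designs use paired t with BH step-up
q-values, with the all-zero-difference edge case defined as t = 0, p = 1.

## Synthetic data: what it emulates, and what it does not

`simulate_tissue` plants neighbourhood structure by scattering cells around
uniformly placed region centres (cells within `neighborhood_radius`, truth
label = nearest centre when regions overlap), draws types from per-motif
mixtures, intensities from per-type lognormals
(`exp(N(log mean, noise_sd))`, so raw values are non-negative like
fluorescence), and shifts motif prevalence by cohort. The default cohort —
24 ROIs of 1200 cells, six types with one 30-fold canonical marker each,
lognormal sd 0.4 (≈8.5 sd of log-scale separation), four motifs with
responder ROIs enriched for lymphoid motifs — is the scale at which all
shipped results are computed. `simulate_expression` adds
`group_shift × noise_sd` to signature genes in responders.
`simulate_label_image` rejection-samples disjoint discs.

Not emulated: optical noise and marker spillover, segmentation errors,
cell-shape and density heterogeneity, spatial gradients within motifs,
marker correlations beyond cell type, and non-normal expression. Passing
recovery tests therefore show the algorithms are implemented correctly and
behave as designed on idealised tissue; they do not guarantee performance on
real CODEX data, where normalization quality and annotation judgement
dominate.

Statistical guarantees are checked by simulation: under null conditions
(identical cohort weights, zero signature shift) the Welch distance test,
the Bonferroni CN family and the median-split Fisher test each reject at
most 5% (+ binomial slack) of 200 replicates; planted effects (1.5 pooled-sd
shift of the ROI-level distance metric at 16 ROIs per cohort — specified at
the metric level because the standardized effect induced through tissue
geometry is emergent and not controllable exactly; 3 noise-sd signature
shift at 20 samples per group) are detected in >= 95% of 200 replicates.

## Problem sizes

Shipped experiments use 2000-cell phenotype-recovery fixtures (10 seeds),
5000-cell CN-recovery fixtures (20 seeds), 200-replicate calibration and
power studies, and a 28,800-cell end-to-end cohort in
`scripts/acceptance.py`; these sizes were chosen so the whole suite runs in
a few minutes on a single CPU while keeping every recovery and calibration
claim at conventional statistical resolution.
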