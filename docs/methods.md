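# Methods

## Scope and data model

The package analyses point-referenced, typed single cells extracted from
multiplexed tissue images. The unit of spatial analysis is the ROI (one
rectangular acquisition window); ROIs nest in samples, samples in clinical
groups. A cell table carries identifiers (`cell_id`, `roi_id`,
`sample_id`, `group`), centroid coordinates in pixels (origin top-left,
x = column, y = row, 0-based, real-valued), pixel area, raw per-marker
intensities (columns named by marker) and, as the pipeline progresses,
normalized intensities (`norm_<marker>`), `cluster_id`, `cell_type` and
`cn_id`. Segmentation is out of scope: the package consumes integer label
masks produced elsewhere.

## Preprocessing

The chain is applied in a fixed, logged order: spillover compensation →
median denoising → linear intensity adjustment → quantification.

**Spillover.** The observed pixel vector is modeled as `o = Sᵀx` where
`S[i, j]` is the fraction of channel *i* signal appearing in channel *j*
(diagonal 1). Compensation solves the per-pixel non-negative least-squares
problem `min‖Sᵀx − o‖², x ≥ 0`. Implementation detail: for a
well-conditioned square `S` the exact linear solution has zero residual,
so whenever it is non-negative it *is* the NNLS optimum and is used
directly; only pixels with negative components (or all pixels when
cond(S) > 1e8) go through the iterative solver. No spillover matrix is
ever invented: compensation is skipped unless a matrix is supplied.

**Median filter.** Per-channel 2-D median, window 3 by default, reflecting
edges. **Linear adjustment.** Per channel, the `low` percentile (default 1)
maps to 0 and the `high` percentile (default 99) to its own pre-adjustment
value, with clipping; percentiles are computed over the whole channel
including background. Note the map is the identity under (0, 100) only
when the channel minimum is 0, which holds for background-bearing IMC
channels. **Quantification.** Mean intensity per channel over each label's
pixels (configurable to median/sum), unweighted pixel centroid, pixel
area; rows ordered by label.

## Phenotyping

**Normalization.** Each marker is divided by its q-th percentile (default
99, linear interpolation) over *all* cells of the cohort pooled across
ROIs, then clipped to [0, 1]. Rare markers (positive fraction near 1%) put
the 99th percentile near the positive/background boundary; the synthetic
expression model (below) was designed so gating stays valid in that
regime.

**Clustering.** k-nearest-neighbour graph (k = 30, Euclidean) on the
normalized *lineage* markers only — functional and disease markers are
excluded from the distance space so phenotype is stable against activation
state. Edges are reweighted by the Jaccard overlap of the two endpoint
neighbour sets and the graph is partitioned with Leiden under the
Reichardt–Bornholdt configuration-model objective, fixed seed. Resolution
defaults to 0.3: at resolution 1 modularity splits large homogeneous
populations on kNN graphs for purely graph-size reasons, which is the
wrong granularity when clusters must map to cell populations; 0.3 keeps
one community per well-separated population while still resolving
populations of ~20 cells. Both k and resolution are exposed. Batch
alignment (Harmony and kin) is not reimplemented; a corrected feature
matrix can be passed via the `features` hook. Embeddings (UMAP) are
visualization-only and not part of the core.

**Annotation.** Pure function of cluster mean expression and an ordered
rule list. A rule fires when all its positive markers exceed and all its
negative markers fall at or below the threshold (default 0.5 on the
normalized scale). A cluster matching more than one *immune* rule is
labeled "mixed immune" — this is how a genuinely mixed lymphoid population
is detected rather than forced into one lineage; otherwise the first
matching rule wins (file order, user-controlled); no match gives
"unassigned", which is reported, never dropped. The default rules for the
bundled panel deliberately omit negative gates on the CD8⁺ T and B rules
so that a CD3⁺CD8a⁺CD20⁺ population triggers the multi-immune fallback.

## Cellular neighborhoods

The CN window of a cell is the cell itself plus its k = 20 nearest
neighbors by centroid distance, computed exactly per ROI (never across ROI
boundaries — ROIs are independent acquisitions); ties at the k-th distance
break by ascending cell id, so the graph is deterministic. Window
composition profiles (fractions over annotated types; fractions, not
counts, so edge cells with smaller windows are comparable) are pooled
cohort-wide and clustered by k-means: Euclidean distance, k-means++
initialization, best of 10 restarts, tol 1e-6, max 300 iterations, fixed
seed; CN ids are 1-based and ordered by descending size. A single pooled
fit (rather than per-group fits) keeps one CN vocabulary for cross-group
comparisons. CNs are annotated by the types whose centroid fraction
exceeds the cohort-global fraction by a factor (default 1.5). Abundance
comparisons use per-sample CN fractions and the Wilcoxon rank-sum test,
raw p-values by default with optional Benjamini–Hochberg.

## Interaction statistics

The directed count statistic for (A → B) in one ROI is the mean, over
type-A cells, of the number of type-B cells inside their CN windows
(window includes the center, so the A → A count of an isolated
monoculture is k + 1). Pairs whose from-type is absent are *absent*, not
zero. Directedness matters: A's neighborhood composition and B's are
different questions, and the statistic is asymmetric.

**Permutation null.** Type labels are shuffled uniformly within the ROI;
positions and the kNN graph stay fixed, and the label multiset is
preserved exactly. Empirical p-values use the add-one estimator
`p_enrich = (1 + #{perm ≥ obs})/(n_perm + 1)` (analogously `p_avoid` with
≤), so `p ≥ 1/(n_perm + 1)` and `p_enrich + p_avoid ≥ 1`. Classification:
interaction if `p_enrich < α`, avoidance if `p_avoid < α`, else ns
(α = 0.05, n_perm = 1000 by default; both configurable). The estimator is
mildly conservative by construction: with discrete count statistics, ties
between observed and permuted values inflate p, and the achievable
rejection level at α = 0.05 with n_perm = 199 is at most 9/200 = 0.045.
Measured over 3000 independent CSR draws the true level is 0.044 ± 0.004.

**Group contrasts.** Two-sample t test (Welch by default) on per-ROI
observed counts per directed pair; zero-variance degenerate pairs get
p = 1 with a flag. **Density quartiles.** Images are ranked by target-type
density (cells/mm² when ROI areas are supplied, else per-image counts) and
split into four equal-size rank bins (remainders to lower bins, density
ties broken by image id); the lowest bin is "absent" only if it contains
zero-density images. Per bin and functional marker, the fraction of cells
above the positivity threshold (default 0.5 normalized) is reported with a
Spearman trend over bin ranks whose two-sided p is computed exactly by
enumerating the 24 rank permutations — the asymptotic approximation is
meaningless at n = 4, and the exact p can never fall below 1/12, so the
trend statistic is descriptive at this bin count. **Composition
correlations.** Anchor-type fraction vs each other type's fraction across
ROIs, Pearson by default with Spearman available (both conventions appear
in practice for this analysis); constant vectors give NA.

## Synthetic tissue generator

The generator defines the study conditions for all validation; none of its
distributions are estimated from any real dataset.

**Cohort structure.** Defaults: 3 control + 15 case samples, 2 ROIs per
sample (36 ROIs), 300×300 px ROIs at 1 µm/px, Poisson(500) cells per ROI,
12 cell types. Group compositions are fixed simplex vectors with immune
fraction ≈ 14.5% (control) vs ≈ 26% (case), epithelial dominant — the
infiltration contrast typical of the glandular tissue this package
targets. Per-ROI seeds derive from the master seed and the (group, sample,
roi) indices via `SeedSequence`, so single ROIs are reproducible in
isolation and cohorts are byte-identical under a fixed spec + seed.

**Placement.** Unstructured types follow a homogeneous Poisson process;
realized type counts are multinomial around the composition. All cells are
hard discs (radius 2 px) placed by rejection sampling with a 100-attempt
cap per cell; saturation raises an explicit packing error naming the ROI.
Attraction pairs use a Neyman–Scott scheme: the planted count of type B is
preserved (composition is never distorted), and `ceil(n_B /
offspring_per_parent)` type-A cells are chosen as cluster parents, each
offspring landing uniformly within the cluster radius of a random parent.
Avoidance pairs resample type-B positions until they clear the exclusion
radius around every type-A cell — exact, not approximate: zero violating
pairs by construction. A type may not be both an anchor and a dependent
(chained structure is rejected at validation). Niche layouts partition the
ROI into rectangles with their own compositions; niche ids are recorded as
ground truth. Note that detectability of planted attraction by the window
count statistic requires a locally contrastive anchor: clustering offspring
around a rare type (e.g. macrophages) is detectable, clustering around a
type that already fills the tissue uniformly (epithelial at 46%) is not,
even though the bivariate pair correlation sees it.

**Expression and rendering.** Marker signal per (type, marker) is
lognormal. Defaults: positives log-location log 20, log-scale 0.15; DNA
log 15; background-negative markers log-location log 0.15 with broad
log-scale 0.8. The broad dim background is deliberate: for a marker whose
positive fraction is ~1%, the cohort 99th percentile can land inside the
background tail, and the mean/99th-percentile ratio of a lognormal falls
with its log-scale, so a broad background keeps negative cluster means
well below the 0.5 gating threshold in that worst case, while tight
positives keep low-expression strata above it. Rendering paints each
cell's drawn mean over its disc pixels, adds constant background (0.3),
applies the spillover forward model and Poisson counting noise per pixel;
stacks are float32. The returned cell table carries the *true* centroids
and drawn (pre-corruption) means, so quantification error is measurable.
What the simulator does not emulate: acquisition physics beyond spillover
+ shot noise, irregular cell shapes, nucleus/membrane structure, spatial
expression gradients within a type, and segmentation errors — so passing
tests demonstrate correctness of the statistics, not robustness to
segmentation artefacts.

## Validation design

Every operation with a nontrivial output is checked against an independent
oracle: brute-force all-pairs sorts for kNN, double-loop recounts for
profiles and interaction tables, per-label pixel averaging for
quantification, forward-model inversion for spillover, sorted-window
medians, and closed-form correlation formulas. Calibration checks
(permutation test under CSR, Wilcoxon under identical compositions,
trend tests under independence) run at the problem sizes used throughout:
300-cell ROIs, n_perm = 199 for calibration/power batches (p resolution
0.005 at α = 0.05), 400 ROIs for the level estimate, 100 replicates for
power. Rejection for the calibration rate follows the standard
discrete-test convention (reject iff p ≤ α), pooled over both cross-type
directed pairs. Recovery checks score the annotated cell types against
ground truth with the adjusted Rand index: annotation is part of the
phenotyping contract, and community detection may legitimately
sub-partition one population between adjacent granularities, which gating
then merges; the raw cluster-level ARI is reported alongside for
transparency.

## Known limitations

* The kNN CN definition is the only neighborhood construction (no
  Delaunay/radius graphs).
* Rule-based annotation assumes markers separate populations at a fixed
  normalized threshold; continuous or gradient phenotypes need custom
  rules.
* The permutation test conditions on the observed point pattern; it tests
  label arrangement, not point-process clustering per se.
* Spillover compensation assumes a known, square, time-invariant matrix.
* The pipeline's determinism guarantee covers stage tables (CSV bytes);
  figure files may differ across matplotlib versions.
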