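# Methods

This note records the models, parameter choices and numerical conventions
behind `tmetopo`, and what the synthetic-data validation does and does not
establish about real tissue data.

## Synthetic data model

The generator (`tmetopo.syndata`) emulates the two assays end to end.

**Layouts.** Cells are points in a half-open pixel field [0, W) × [0, H)
(origin top-left, x = column, y = row). Background cells are placed by
rejection sampling (dart throwing) under a global minimum centroid
separation; phenotypes are drawn as a single multinomial over the supplied
composition, as the first draw from the call's seeded generator, so an
independent oracle with the same seed policy reproduces the counts.
Planted aggregates (TLS-like follicles, niche disks) draw member positions
uniformly within a disk. Infeasible packings fail loudly after a bounded
number of attempts per cell rather than looping forever.

*Minimum separation.* The default is 6 px against a rendered nucleus
radius of 1.5 px (a 3×3 raster). This guarantees — including worst-case
centroid rounding — that no two nucleus rasters are 8-connected, so
segmentation ground truth is unambiguous: every planted cell is exactly
one connected component. Larger nucleus radii at this separation would
merge rasters and make exact-count recovery impossible by construction.
Dense follicle fixtures lower the separation to 2–4 px explicitly, which
matches the packing of real lymphoid aggregates better than the sparse
default.

**Images.** Each cell contributes a nucleus disk (nucleus channel) and a
whole-cell disk of radius 4 px (all other channels), scaled by its
phenotype's per-channel intensity profile. There is no public quantitative
intensity model for this imaging modality, so profile magnitudes are free
parameters with defaults around 8–10 counts on the dominant lineage marker
and zero elsewhere; what matters downstream is contrast, not absolute
scale. The observed image is the true image mixed through the spillover
matrix (row-stochastic crosstalk, entry (i, j) = fraction of channel-i
signal read in channel j), optionally with Poisson shot noise and a
configured rate of additive hot pixels.

**Counts.** Gene counts are negative binomial with per-phenotype mean
profiles and a shared dispersion θ (variance μ + μ²/θ; θ → ∞ recovers
Poisson, checked by a moment test). Defaults: ~300 background genes with
log-normal means shared across phenotypes, 8 named marker genes per
phenotype at a 100-fold mean contrast (20 vs 0.2), mitochondrial genes
(`MT-` prefix) calibrated so the expected mitochondrial count fraction
matches the requested value (default 5 %), and doublets formed by adding a
second random parent's counts to a flagged barcode. Doublets exist only in
the count arm; the imaging arm's ambiguities (touching cells) are governed
by the separation parameter instead. FFPE-specific artifacts — RNA
degradation, ambient RNA, batch effects — are deliberately not simulated;
batch integration is out of scope.

**What passing tests show.** Recovery results on these fixtures establish
that the statistics are implemented correctly and are well calibrated
under their own assumptions (independent NB noise, disk-shaped cells,
planted circular aggregates). They do not establish robustness to
segmentation errors from irregular morphology, marker spillover beyond the
linear model, doublet-driven intermediate phenotypes, or inter-patient
heterogeneity — on real cohorts those remain the user's responsibility.

## Imaging preprocessing

Processing order is fixed: compensation → denoising → contrast →
segmentation → quantification.

* **Compensation** solves, per pixel, min‖xᵀS − oᵀ‖₂ subject to x ≥ 0.
  The unconstrained solve is used wherever it is already non-negative
  (the two coincide there); only pixels with negative leakage fall back to
  NNLS. Condition numbers above 1e8 raise an error naming the most nearly
  collinear channel pair.
* **Denoising** replaces any pixel exceeding its 3×3 neighborhood median
  (symmetric border reflection) by more than a threshold (default 50 raw
  counts) with that median. This targets isolated hot pixels; it is a
  single-pass filter and intentionally not iterated.
* **Contrast** clips each channel to a percentile window (default
  [0, 99]) and rescales to [0, 1]; degenerate channels become zero with a
  warning. Percentiles are always linear interpolation between order
  statistics (numpy default), stated once here and used everywhere.
* **Segmentation** thresholds the nucleus channel, takes 8-connected
  components as seeds, and expands each seed to a whole-cell footprint of
  fixed radius (default 5 px) with nearest-nucleus assignment via the
  Euclidean distance transform (ties resolve deterministically by scan
  order). The nucleus threshold and expansion radius are exposed as
  configuration because no published values exist for them. Connected
  components in membrane/lineage channels whose centroid lies farther than
  15 px (configurable) from the nearest nucleus centroid are flagged as
  acquisition artifacts, measured centroid-to-centroid.
* **Quantification** takes per-cell mean intensity per channel, divides
  each channel by its 99th percentile across cells, clips to [0, 1]. The
  output is invariant to mask relabeling.

## Phenotyping

Graph clustering is one operation serving both arms: exact Euclidean kNN
(k = 100 for marker tables, k = 20 for PCA embeddings by default), edge
weights by Jaccard similarity of the self-inclusive neighborhoods, pruning
below 1/15, then Leiden modularity (RB configuration) at the configured
resolution with a fixed seed. Cluster ids are renumbered by decreasing
size, so partitions are fully deterministic. The community algorithm is a
design choice (the Louvain/Leiden family is standard for this task);
resolution defaults are 1.2 (transcriptomic) and 1.0 (imaging).

QC uses strict inequalities exactly: remove genes covered by fewer than 3
cells, then remove cells expressing < 500 or > 5000 genes, containing
< 400 or > 25 000 total counts, or with mitochondrial fraction > 0.15 —
boundary cells survive. The filter is one pass (gene filter, then cell
filters computed on the gene-filtered matrix), matching the quoted
procedure; iterating to a fixpoint would change the semantics.

The HVG ranking reimplements the vst statistic: a lowess trend (span 0.3)
of log10 variance on log10 mean of raw counts predicts each gene's
expected standard deviation; counts standardized by it are clipped at √N
and genes are ranked by the variance of the clipped values. This is
implemented directly (statsmodels lowess) rather than delegated, and is
validated against an independent reimplementation in the tests.

PCA z-scores the HVG submatrix (clipped at 10), decomposes by full SVD,
and fixes signs so each component's largest-magnitude loading is positive
— bit-reproducible embeddings. Rank-deficient inputs truncate with a
warning.

Marker ranking is one-vs-rest two-sided Wilcoxon rank-sum with pre-filters
on detection fraction (≥ 0.25 in either group) and absolute log fold
change (≥ 0.25). Log fold change is ln((mean(expm1 x)+1)/(mean(expm1 x)+1))
between groups on the log-normalized matrix — stated explicitly because
conventions differ between tool versions. P-values are exact (no ties,
both groups ≤ 10) or normal-approximated with tie correction, and
BH-adjusted within each cluster's tested genes.

Annotation assigns each cluster the marker set with the highest mean
z-scored expression; ties break alphabetically with a warning.

## Enrichment statistics

Ro/e divides observed counts by the chi-squared independence expectation
E(c, s) = n_c n_s / n. Entries with zero expectation are reported as NaN
and flagged, never as infinity. The conservation identity
Σ_s E(c,s)·Roe(c,s)/n_c = 1 holds exactly and is tested property-style.

ssGSEA ranks genes per sample (ties by average rank, descending walk with
a deterministic tie order) and scores Σ_i [P_in^w(i) − P_out(i)], where
P_in^w is the |rank|^α-weighted ECDF over set members (α default 0.25) and
P_out the unweighted ECDF over non-members. Scores are raw by default; an
option divides by the score range across the supplied samples. Being
rank-based, scores are invariant under strictly monotone transforms — note
that float arithmetic can break strict monotonicity for subnormal values,
which is a property of the inputs, not the statistic.

The tissue-resident-macrophage signature ships as TIMD4, LYVE1, FOLR2,
CCR2 plus an MHC class II expansion (HLA-DRA, HLA-DRB1, HLA-DPA1,
HLA-DPB1, configurable); the class II family has no canonical member list,
and the symbol "TIDM4" occasionally seen in print is a transposition of
TIMD4. M1/M2 polarization sets are not bundled — supply them as GMT.

## Spatial topology

Graphs are built per image (neighbors never cross image boundaries) with
exact Euclidean kNN, ties broken by cell id; distances are µm via the ROI
pixel size. The CN window includes the center cell (k + 1 cells, k = 20
default) — the natural reading of "a cell and its 20 nearest neighbors" —
with a flag to exclude it. Collagen-dominant structures participate as
pseudo-cells of category "collagen I", so matrix deposition shapes the
neighborhoods alongside the cell clusters. CN composition vectors are
clustered by K-means (k-means++ init, 10 restarts, fixed seed, best
inertia kept); k_cn = 15 in the reference configuration.

The interaction test keeps the image's graph fixed and permutes phenotype
labels, which controls for both the tissue's connectivity and its
type abundances. Add-one p-value estimators keep p in (0, 1]; α defaults
to 0.01. The observed statistic equals a brute-force all-pairs double loop
exactly (tested); the permutation distribution is computed vectorized in
chunks. With a single phenotype the null is degenerate and p = 1 — the
classification is "none", and pairs involving a phenotype absent from an
image are recorded as "absent" rather than silently dropped.

Patch detection is DBSCAN over the target phenotypes (defaults: B and
memory CD4⁺ T cells; eps 20 µm; min_size 20, the point itself included in
its own neighborhood — sklearn's convention). Border cells join the first
core cluster reaching them in cell-id order, making results deterministic.
Patch area is the alpha-shape of member centroids with α = eps, computed
as the summed area of Delaunay triangles with circumradius ≤ eps; patches
with < 3 members have zero area. Patch density divides patch count by the
full ROI area in mm². All patch parameters are configuration; no published
values exist for this analysis.

## Pipelines and reproducibility

`PipelineConfig` holds every threshold with the reference defaults and
round-trips JSON losslessly, rejecting unknown keys. `run_imc` and
`run_rna` write CSV outputs plus a manifest with the config hash, seed,
package versions and SHA-256 of every output; under a fixed seed, reruns
are byte-identical (tested). Stage failures abort with stage-named errors;
an empty post-QC matrix is a graceful warning stop, not a crash. Exit
codes distinguish configuration (2), data (3) and stage (4) errors.

Problem sizes in the tests and the acceptance script — 2000-cell count
matrices, 200–600-cell images, 500 permutation-null images — were chosen
so each statistical check has comfortable power (e.g. ±3 Monte-Carlo
standard errors around the nominal 5 % rejection rate) while the whole
validation runs in well under a minute; recovery results are flat in size
beyond this range.

## Known limitations

* The segmentation model (disk expansion around nucleus seeds) suits the
  synthetic morphology; real tissue needs membrane-aware or learned
  segmentation, which is out of scope by design.
* One-pass QC is not guaranteed idempotent on adversarial matrices
  (removing cells can drop a gene below the coverage threshold); it is
  idempotent on all study fixtures and matches the quoted procedure.
* Batch integration, UMAP visualization, ligand–receptor inference and GO
  enrichment are out of scope; single-batch synthetic data stands in for
  the integrated cohort.
* Exact Wilcoxon p-values require tie-free small groups; with ties the
  normal approximation with tie correction is used, which is standard but
  approximate.
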