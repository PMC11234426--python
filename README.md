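# tmetopo

Organ-specific spatial tumor-microenvironment (TME) topology from
multiplexed imaging and single-nucleus count matrices.

Metastatic tumors at different anatomical sites respond very differently to
immunotherapy, and part of the explanation is structural: *which* immune
cells infiltrate a lesion, and *how they are arranged* — B/T-cell
aggregates resembling tertiary lymphoid structures (TLS), collagen-walled
exclusion zones, macrophage niches. `tmetopo` is a toolkit for quantifying
that structure from two complementary assays:

* **multiplexed imaging** (IMC-style): ~40-channel images of tissue
  regions of interest, one channel per metal-tagged antibody, ~1 µm pixels;
* **single-nucleus RNA counts** (FFPE-compatible droplet protocols):
  gene-by-cell integer matrices with per-cell site/patient metadata.

Because raw clinical datasets of this kind are rarely deposited, the
package ships a first-class synthetic-data generator (`tmetopo.syndata`)
that plants known phenotypes, site compositions, TLS-like aggregates,
spillover and noise — so every downstream statistic can be validated
against ground truth.

## What it computes

**Imaging arm** (`imcproc`, `phenotype`, `spatial`):
compensation of channel spillover by per-pixel non-negative least squares
(min‖xᵀS − oᵀ‖₂, x ≥ 0); hot-pixel median denoising; percentile contrast
normalization; nucleus-seeded cell segmentation with a 15-px
artifact-distance rule; per-cell marker means normalized to the channel
99th percentile; PhenoGraph-style clustering (kNN → shared-nearest-neighbor
Jaccard weights → Leiden modularity).

**Spatial statistics** (`spatial`):

* *Cellular neighborhoods (CN)*: for each cell, the phenotype composition
  of the window {cell ∪ 20 nearest neighbors}, K-means-clustered (k = 15)
  into recurring tissue motifs over the cell clusters along with collagen I.
* *Interaction/avoidance testing*: for each image and ordered phenotype
  pair (A, B), the observed statistic is the mean number of B neighbors
  per A cell; the null permutes phenotype labels over the image with the
  graph fixed. Add-one estimators give
  p_interact = (1 + #{perm ≥ obs}) / (n_perm + 1), p_avoid analogously.
* *TLS-like patch detection*: density-based clustering (DBSCAN semantics)
  of B / memory-CD4 T cells, patch area by alpha-shape, patch density per
  mm² of ROI.

**Enrichment** (`enrich`):

* *Ro/e*: observed/expected cell counts per (cluster, site) with
  E(c,s) = n_c·n_s/n under the chi-squared independence model; Ro/e > 1
  flags tissue enrichment.
* *ssGSEA*: rank-based running-sum score
  Σ_i [P_in^w(i) − P_out(i)] with |rank|^α-weighted in-set ECDF (α = 0.25),
  plus mean-z signature scores (e.g. a tissue-resident-macrophage
  signature: TIMD4, LYVE1, FOLR2, CCR2 and MHC class II genes).
* Site-wise frequency comparisons: Wilcoxon rank-sum (exact for small
  groups) / Kruskal–Wallis with Benjamini–Hochberg adjustment.

**Transcriptomic arm** (`phenotype`): QC with strict thresholds (genes
detected in < 3 cells removed; cells with < 500 or > 5000 genes, < 400 or
> 25 000 UMIs, or > 15 % mitochondrial content removed), library-size
log-normalization, 2000 highly variable genes by the vst
mean–variance-trend ranking, 20 PCs, Leiden clustering at resolution 1.2,
and one-vs-rest Wilcoxon marker ranking (min.pct = 0.25,
logfc.threshold = 0.25).

## Worked example

Plant a cohort with plasma cells 3× over-represented in the adrenal site,
then ask Ro/e which site each phenotype prefers:

```python
import pandas as pd
from tmetopo import syndata, enrich

prof, markers = syndata.default_count_profiles()
comp = syndata.default_rna_site_composition()
adata, truth = syndata.generate_counts(5000, comp, prof, seed=1)
obs = pd.crosstab(adata.obs["phenotype"], adata.obs["site"])
print(enrich.roe(obs).ratio.round(2))
```

```
site        adrenal  brain  liver  lung
phenotype
B              1.67   0.33   0.42  1.57
T              1.58   0.54   0.54  1.33
epithelial     0.49   1.42   1.34  0.76
macrophage     0.73   1.09   1.17  1.02
plasma         2.44   0.32   0.37  0.87
```

The planted structure is recovered: plasma cells are strongly enriched in
the adrenal site (Ro/e = 2.44, the row maximum), B and T cells favor the
immunogenic sites (adrenal, lung), and epithelial cells dominate the
immune-poor brain/liver lesions.

Detect a planted TLS-like aggregate in an imaging layout:

```python
from tmetopo import spatial
from tmetopo.syndata import AggregateSpec, generate_layout

cells, _ = generate_layout(
    400, site="adrenal",
    composition=syndata.default_site_composition()["adrenal"].to_dict(),
    aggregates=[AggregateSpec(center=(150, 150), radius=35, n_cells=70,
                              composition={"B": 0.6, "memory CD4 T": 0.4})],
    shape=(384, 384), seed=2)
patches = spatial.detect_patches(cells.assign(roi_id="roi0"),
                                 {"B", "memory CD4 T"}, eps=20, min_size=20,
                                 roi_area_mm2=0.384 ** 2)
```

This finds exactly 1 patch with 61 member cells, alpha-shape area
2901 µm², density 6.8 patches/mm², composed of 62 % B cells and 38 %
memory CD4⁺ T cells — the planted follicle.

A command-line interface wraps the full pipelines:

```bash
tmetopo syn --seed 1 --out fixtures          # synthetic ROIs + counts
tmetopo imc --input-dir fixtures --output-dir out_imc
tmetopo rna --input-dir fixtures/counts --output-dir out_rna
tmetopo report --output-dir out_imc          # summary plots
```

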