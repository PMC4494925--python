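# gliomosaic

Integrative multi-omic analysis of **spatial intratumor heterogeneity in
glioblastoma**. Surgical multi-sampling studies take several biopsies per
patient along a core-to-periphery axis — necrotic zone (NZ), tumor zone
(TZ), interface (I), peripheral brain zone (PBZ) — plus reference control
brains, and profile each biopsy on multiple molecular levels.
`gliomosaic` provides the full analysis chain for such cohorts, for
computational biologists who want a tested, reproducible implementation:

* **Copy-number profiles** — weighted-median normalization, Haar-wavelet
  segmentation with per-scale FDR control, 4-state calling
  (−1 loss / 0 normal / +1 gain / +2 amplification) at log2 thresholds
  −0.30 / +0.30 / +1.0, the "<1% altered ⇒ potential normal brain" rule,
  Ward clustering of call profiles, and minimal common regions (MCRs) with
  a cyclic-shift permutation null.
* **Sample structure** — PCA (exact SVD), hierarchical clustering on
  principal components (HCPC, k = 4), and per-gene informativeness
  score(g) = |r(x_g, PC1)|, used to reduce to the top 8000 genes.
* **Differential expression** — gene-wise Welch one-way ANOVA across
  clusters, Benjamini–Hochberg adjustment, max pairwise fold change;
  DE ⇔ adjusted p < 0.001 and |FC| > 2.
* **Signed co-expression network** — adjacency a_ij = ((1+r_ij)/2)^12,
  topological overlap TO_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
  branch-wise module detection (min module size 175), module eigengenes,
  module membership (MM), gene significance GS = −log10 p_adj, permutation
  module significance, and upper-quartile "core modules".
* **Methylation integration** — β = Max(M,0)/[Max(M,0)+Max(U,0)+100],
  kNN imputation, per-gene expression–methylation Pearson correlation with
  anti-correlation at r < −0.6, and a bootstrap enrichment curve (n = 1000,
  median and 99% CI) of the anti-correlated percentage among top-ranked
  genes.
* **Signature & subtypes** — 25 genes per significant module by rank
  product of eigen score and MM among DE genes; structure-preservation
  check; per-sample subtype assignment (Proneural / Neural / Classical /
  Mesenchymal) by centroid correlation or single-sample enrichment; ΔΔCt
  utility for qPCR validation.
* **Synthetic cohort generator** — a first-class module that plants zone
  gradients, co-expression modules with hub genes, methylation-silenced
  genes, patient-shared CNAs and zone-dependent subtypes, with complete
  ground truth, so the whole chain is testable offline.

## Worked example

```python
import gliomosaic as gm

result = gm.run_pipeline(gm.PipelineConfig(outdir="results", seed=1))

counts = result.manifest["counts"]
print(counts["significant_modules"], "significant modules of", counts["modules"])
print(counts["signature_genes"], "signature genes; anticorr:",
      counts["anticorr_genes"], "genes")

curve = result.tables["curve"]
print(f"peak {curve.peak_percent:.0f}% anti-correlated at top {curve.peak_size} genes")
```

On the default synthetic study (10 patients × 4 zones + 4 reference
brains, 12000 genes) this prints:

```
4 significant modules of 6
100 signature genes; anticorr: 360 genes
peak 27% anti-correlated at top 100 genes
```

meaning: module detection on the 8000 most informative genes found 6
co-expression modules of which 4 are significantly zone-associated; the
key-gene signature holds 25 genes from each (100 total); 360/12000 genes
(3.0%) are methylation-silenced (r < −0.6), and their share rises to 27%
among the 100 most PCA-informative genes — far above the ~3% resampling
null, the hallmark of epigenetic control of the zone gradient. The
written outputs (`results/*.tsv`, `manifest.json`) include per-sample CNA
calls and alteration percentages, HCPC clusters, the DE table, module
tables, the enrichment curve, the signature and subtype assignments; a
re-run with the same seed is byte-identical.

A thin CLI mirrors the stages:

```bash
gliomosaic all --outdir results --seed 1
gliomosaic simulate --outdir cohort --seed 2 --n-patients 10
gliomosaic network --outdir results --beta 12 --min-module-size 175
```

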