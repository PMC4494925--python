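# Methods

`gliomosaic` implements an integrative multi-omic analysis of spatial
intratumor heterogeneity in glioblastoma, in which each tumor is sampled
along a core-to-periphery axis — necrotic zone (NZ), tumor zone (TZ),
interface (I) and peripheral brain zone (PBZ) — together with reference
control brains (REF). The analysis chain is: copy-number profiling →
sample-structure discovery → differential expression → signed co-expression
networks → methylation anti-correlation → key-gene signature and
transcriptional subtype assignment. A synthetic cohort generator with full
ground truth drives development and testing; no external data are required.

## Synthetic cohort model

Expression (log2 scale) for gene *g* in module *m* and sample *s* is

    x_gs = b_g + l_g · d_m(s) + ε_gs,   ε_gs ~ N(0, σ²)

with per-gene baseline `b_g ~ N(7, 1)`, loading `l_g ~ U(0.8, 1.2)` and
residual SD `σ = 0.35`, typical of log-scale two-color microarray data.
The module driver is

    d_m(s) = g_m · s_m(z(s)) + a_{m,p(s)} + u_m(s)

where `z` is the ordinal zone axis (NZ=0, TZ=1, I=2, PBZ=3, REF=3.5),
`s_m` a monotone transition shape, `g_m` the signed gradient strength,
`a_{m,p} ~ N(0, 0.15²)` a per-patient intercept, and `u_m(s) ~ N(0, 0.5²)`
a zone-independent module-private factor (each module's own biology).

Two design points matter and were choices we made deliberately:

* **Transition shapes, not a common linear ramp.** If every driver were
  linear in `z`, all same-direction modules would be correlated near 1 and
  would be a single co-expression module by construction — no network
  method could separate them. Real zone-responsive programs switch at
  different boundaries (necrosis, tumor mass, infiltration margin), so the
  four strong modules use sharp monotone transitions at `z≈1`, `z≈2` and
  `z≈3` (with a small linear tail to keep drivers strictly monotone):
  turquoise (down, early), blue (up, early), brown (up, mid), green (up,
  late). The three weak modules (yellow, red, black) carry small gradients
  (|g| ≤ 0.25) and are held together by their private factors. A
  transition shape is reused with the same sign only when at least one of
  the pair is latent-dominated.
* **A hub tier.** The first 25 genes of each module are "hubs": loading
  2.0, residual SD 0.2, plus an admixture of the overall linear gradient
  (30% of the module's own strength). Hubs are therefore simultaneously
  module-central (high module membership) and informative for the global
  sample structure (high PCA score) — the profile of key heterogeneity
  genes — and they define the planted truth for signature recovery.

Methylation is simulated as one promoter CpG per gene. For the 3% of genes
flagged as methylation-silenced (drawn preferentially from high-gradient
genes, 60% from the top-600 by absolute gradient effect), the β-value is a
logistic function of centered expression, `β = clamp01(expit(−1.2·(x−x̄)) +
N(0, 0.05))`, which yields Pearson r(expression, β) < −0.6 for essentially
all flagged genes at the default noise. Other genes get independent
baselines `U(0.05, 0.95)` with SD-0.05 noise. 1% of entries are masked to
exercise imputation.

Copy-number tracks place 4000 probes over the 22 autosomes proportional to
GRCh37 lengths. Every patient shares a whole-chr7 gain and whole-chr10
loss (the canonical glioblastoma events) plus two private random events;
NZ/TZ samples carry all template events, interface samples each event with
probability 0.6, and PBZ/REF samples none. Probe log2 ratios are the state
means (−0.55, 0, 0.45, 1.5 — single-copy events at ~60% purity) plus
N(0, 0.15) noise.

Each sample's transcriptional subtype (Proneural, Neural, Classical,
Mesenchymal) is drawn from zone-dependent propensities — core zones favor
Classical/Mesenchymal, peripheral zones Neural/Proneural, reference brains
Neural — and imprinted as `0.6 ×` the subtype centroid on 400 dedicated
background genes. Centroids are redrawn until pairwise |r| < 0.3.

Generator defaults were calibrated once, before the test suite was frozen,
so that the planted structure is recoverable by the analysis the package
implements (zone ARI, module ARI, signature recovery); they aim for
testability at the study's scale, not for biological realism of effect
sizes, which the source study does not report.

**What the generator does not emulate:** probe sequences and hybridization
artifacts, batch effects, histological composition, tumor purity gradients
within a zone, copy-number influence on expression (the omics layers are
generated independently except where stated), and non-promoter CpGs.
Passing tests therefore demonstrate correctness of the analysis chain on
data satisfying its assumptions, not robustness to every artifact of real
arrays.

## Copy-number analysis

Tracks are normalized by merging duplicate probes (median) and subtracting
the weighted median of log2 ratios. Segmentation is Haar-wavelet based:
at dyadic half-windows `h = 1..128` the step coefficient at each boundary
is z-scored against a robust noise estimate (MAD of lag-1 differences),
boundaries passing a per-scale Benjamini–Hochberg step-up at FDR 0.05 are
reduced to local maxima, and scales are unified fine-to-coarse (a coarse
breakpoint is dropped within `h` of a finer one). Segments are called by
fixed log2 thresholds −0.30 / +0.30 / +1.0 (loss / gain / amplification);
a mixture-model caller would need parameters the source analysis does not
expose, whereas fixed thresholds are transparent, configurable and
testable. Samples with less than 1% of altered probes are flagged as
potential normal brain. Call profiles are clustered by Ward linkage on
per-probe states. Minimal common regions use per-probe alteration
frequencies (losses and gains separately) against a null built by cyclic
within-chromosome shifts of each sample's calls, which preserves each
sample's alteration load and segment-length spectrum; regions are runs of
probes above the chromosome-wise null quantile, with an empirical p from
the permutation maxima.

## Sample structure

PCA is an exact SVD of the centered (optionally unit-variance) sample ×
gene matrix; component signs are fixed by making each loading vector's
largest entry positive. HCPC retains the smallest number of components
covering 80% of variance (capped at 10) and applies Ward clustering, with
the tree cut at k = 4 and labels renumbered along PC1 so cluster 1 is
always the same end of the gradient. Gene informativeness is
|r(gene, PC1)| — the single-component specialization of the eigen-marker
score — and the analysis proceeds on the top 8000 genes. Genes are
standardized before PCA by default; both modes are supported.

## Differential expression

Welch's heteroscedastic one-way ANOVA per gene across the HCPC clusters
(Welch–Satterthwaite degrees of freedom), Benjamini–Hochberg adjustment,
and the maximum pairwise fold change `2^|Δmean|` on the log2 scale with
the attaining pair reported. The DE call is adjusted p < 0.001 and
|FC| > 2. Genes failing preconditions propagate NA rather than being
dropped, keeping row alignment.

## Co-expression network

Signed adjacency `a = ((1+r)/2)^12`, topological overlap with the standard
normalization `TO_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, and
average-linkage clustering of `1 − TO`. Module detection is a
variable-height branch search validated against the TO data itself,
because raw merge heights are unreliable on chained average-linkage trees:
a branch split is accepted when mean between-branch TO < 0.7 × the smaller
within-branch mean; sub-minimum fragments are shed while their TO to the
branch core stays below 0.5 × core cohesion; and an accepted module must
have mean within-TO above 2 × its TO to the remaining genes, which leaves
structureless input almost entirely unassigned. The minimum module size is
175; a static height cut is available as an option. Eigengenes are the
first principal component of the gene-standardized module submatrix,
oriented positively along the module mean profile. Module membership is
correlation with an eigengene; gene significance is −log10 of the BH
adjusted ANOVA p (capped at 1e−16, so GS ≤ 16); module significance is a
one-sided permutation test of mean GS over 1000 gene-label permutations at
α = 0.05; the core module is the upper quartile by own-module membership.

## Methylation integration

β = Max(M,0)/[Max(M,0)+Max(U,0)+100] from raw intensities; k-nearest-row
imputation (k = 10, Euclidean over co-observed columns, clamped to [0,1]);
per-gene Pearson correlation between expression and β over shared samples
(NA below 3 complete pairs), with anti-correlation at r < −0.6. The
enrichment curve evaluates the percentage of anti-correlated genes among
the top-n genes by PCA informativeness for n = 100..1000 step 10 and 50
log-spaced sizes up to the full set, against a null of 1000 uniform
random size-n subsets drawn without replacement (realized as exact
hypergeometric draws of the flagged count, which is the same
distribution); the null median and equal-tailed 99% interval are reported
and a size is significant when the observed percentage exceeds the upper
bound.

## Signature and subtypes

From each significant module, the DE-flagged members are ranked by the
product of their eigen-score rank and own-module membership rank, and the
top 25 are taken (ties by gene id). The DE table used is the omnibus
Welch ANOVA by default: cluster numbering orientation follows the sign of
PC1 and modules transition at different zone boundaries, so a fixed
pairwise cluster contrast would starve some modules of candidates; any
pairwise contrast can be requested instead. A structure check clusters
samples on the signature submatrix (correlation distance, average linkage)
and reports the adjusted Rand index against the HCPC reference.

Subtype scores support two modes: correlation of the sample profile with
subtype centroids over the centroid genes (a sample lying exactly on a
centroid scores 1), and a single-sample weighted Kolmogorov–Smirnov
enrichment score over subtype gene sets with genes ranked by per-gene z
(weight |z|). Assignment is the per-sample argmax, ties resolved in the
declared subtype order (Proneural, Neural, Classical, Mesenchymal); the
set of distinct subtypes per patient quantifies intratumor subtype
heterogeneity. A ΔΔCt helper computes relative qPCR quantities.

## Numerical and reproducibility choices

All randomness is seeded; the pipeline derives independent per-stage
substreams from one seed and records them in a JSON manifest with output
hashes, so a re-run is byte-identical. TSVs are written with a fixed float
format. Ties are always broken deterministically (lexicographic gene id;
first declared subtype). Correlations of zero-variance vectors yield NA
and are never flagged. Default problem sizes (12000 genes, 44 samples,
4000 probes, 1000 permutations/bootstrap draws) run in about a minute on
one CPU; tests use these defaults for the recovery checks and scaled-down
cohorts elsewhere.

## Known limitations

Module detection assumes modules are branch-shaped in the average-linkage
tree of 1 − TO; heavily overlapping modules merge (the between/within
threshold of 0.7 is the knob). Topological overlap inflates the
similarity of very low-connectivity genes toward large modules, which is
why validation uses TO contrasts rather than merge heights. The
permutation null for module significance compares a module's mean GS with
the average gene, so when nearly all analyzed genes are zone-associated a
genuinely associated but below-average module can be non-significant. The
subtype enrichment mode is a single-sample score, not a trained
classifier; with real data a published centroid set should be supplied.
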