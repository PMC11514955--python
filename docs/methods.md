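# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic data generator does and does not emulate, and the
package's known limitations. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Statistical core (`imgene.stats`)

Categorical associations use Fisher's exact test (two-sided, summing all
hypergeometric tables with probability at most the observed one — the common
convention) for 2×2 comparisons, and Pearson's chi-squared without continuity
correction for r×c tables. Both are exposed because the published cohort
table's p-values (0.775, 0.985, 0.262) match the uncorrected chi-squared
test, while the accompanying text names Fisher; the package defaults to
Fisher for gene-level 2×2 tests and uses chi-squared when reproducing the
cohort table. Continuous two-group comparisons use the Mann–Whitney U test
(exact for small tie-free samples, normal approximation with tie correction
otherwise); multi-group, Kruskal–Wallis; correlations, Spearman. Multiple
testing is controlled by Benjamini–Hochberg q-values with a q < 0.1
significance convention.

Logistic models are fitted by maximum likelihood (statsmodels, tolerance
1e−8, up to 100 iterations); separation is detected from convergence failure
or diverging coefficients and flagged rather than raised. The published
multivariable nodal-metastasis model ships as a fixed coefficient vector
(intercept −3.07; slopes for nodule type, tumor size, histologic subtype,
STAS, VPI, LVI and seven gene indicators). The tumor-size slope is used
exactly as printed (−0.035) even though the printed odds ratio (1.036)
implies the opposite sign; we preserve the printed coefficient and note the
conflict rather than resolving it. Negative binomial regression, mentioned
once alongside the logistic analysis, is out of scope: the outcome is
binary.

## Synthetic cohort generator (`imgene.simulate`)

The generator emulates the study's *conditions*, not its raw data: 257
patients (53 pN+), clinical covariates drawn at the published group rates
(solid nodule 52.9%/90.6%, LVI 25.5%/71.7%, …), per-gene Bernoulli mutations
at published or declared group frequencies (TP53 0.37/0.55, PIK3CG
0.005/0.075, ATM 0.03/0.12 — ATM's frequencies are declared defaults since
only its direction is reported), nonsynonymous counts Poisson with mean =
group TMB median × 1.21 Mb, and VAFs from a clonal Beta(10,15) / subclonal
Beta(2,12) mixture. Mixture weights (0.40 pN−, 0.43 pN+) were calibrated
once, by simulating the generator, so that cohort-median MATH lands near the
published group medians (45.7 / 53.5). Within a patient the mixture is
sampled *balanced* (each tumor receives its expected share of subclonal
variants, the fractional remainder randomized): with only ~4–6 variants per
tumor, iid component draws make per-patient MATH strongly bimodal and the
cohort median an unstable estimator.

The mIHC subset is chosen by the package's own propensity matching (1:1,
caliper 0.2 SD of the logit score, on age/sex/smoking), 46 case–control
pairs ≈ 92 patients, each with 5–8 ROIs (uniform; mean ≈ 6.5, ≈ 598 ROIs).
Within a 400 × 400 µm ROI, epithelial cells form Thomas-process nests
(Poisson(3)+1 parents, 40 µm scatter); macrophages sit within a 25 µm
contact scale of nest centers with probability 0.60 in pN+ vs 0.25 in pN−
tissue (the planted interaction signal); Tregs aggregate into 25 µm niches
(the planted immune-suppressed neighbourhood); other populations are
uniform. Per-patient composition is Dirichlet around the group target
(concentration 500), with group targets chosen so immune infiltrate,
macrophage and Treg fractions match the published group values. Marker
intensities are log-normal (σ = 0.3) around a metacluster signature
(positive markers 20, secondary 15, negative 0.05) with per-batch
multiplicative shifts (4 batches, log-σ 0.15).

Defaults were sized for desk-scale runs: ~250 cells per ROI (~1600 per
patient, ~1.5 × 10⁵ cells per cohort, a few seconds to generate). The
density is deliberately high enough that the rarest planted population
(Tregs at 0.29% of cells in pN− tissue) is estimable per patient; far
smaller ROIs would leave < 1 expected Treg per patient and no per-patient
fraction to test.

What the generator does **not** emulate: raw images and segmentation error,
spatially varying cell density or tissue architecture beyond nests/niches,
marker spillover or autofluorescence, panel-specific gene coverage
differences, clonal phylogenies behind the VAF distribution, and any
correlation between genomic and spatial planted effects beyond their shared
dependence on pN status. Passing recovery tests therefore demonstrate that
the pipeline detects effects of the published size under clean, well-specified
noise — not performance on real tissue.

## Phenotyping (`imgene.phenotyping`)

Intensities are asinh-transformed (cofactor 1) and z-scored per marker;
zero-variance markers get z = 0 with a log entry. PCA keeps up to 20
components (with 6 markers, all 6). Batch correction runs in PC space as
iterative soft clustering plus per-batch-per-cluster centroid alignment,
with one addition: soft responsibilities are re-weighted by
(expected/observed batch mass per cluster)^θ (θ = 2). Without that
diversity penalty a strong batch effect produces batch-pure clusters whose
batch centroid coincides with the pooled centroid, making alignment a no-op;
the penalty forces mixed clusters, after which alignment removes the shift
(verified by a classifier-predictability test in the suite). A single batch
yields the identity correction.

Metacluster assignment is deterministic gating on the transformed z-scores
with threshold z > 0.5 and fixed precedence: PANCK⁺ → epithelial (PD-L1⁺
subsplit), else CD68⁺ → macrophage (PD-L1⁺ subsplit), else CD4⁺FOXP3⁺ →
Treg, else CD4⁺/CD8⁺ → T cells, else any remaining marker⁺ → other immune,
else other. The threshold is a declared default: the original supervised
phenotyping software is not reproducible here, and the 9-label set is
derived from the 6-marker panel's resolvable populations. An unsupervised
route (cluster-then-annotate) can be composed from the embedding utilities,
but gating is the default because it is deterministic and auditable.
"Immune" denominators exclude the two epithelial labels and the
marker-negative remainder. The 2-D embedding is presentation-only and enters
no statistic.

## Spatial analysis (`imgene.spatial`)

Cell graphs are Delaunay triangulations per ROI (duplicate coordinates
jittered by 1e−6 µm; < 3 or collinear points fall back to nearest-neighbour
edges); interaction partners prune edges above 4 µm. Neighbourhood windows
default to the 20 nearest cells including the center (k-NN); a
radius-based mode (primary neighbours within 4 µm plus their secondary
neighbours) is available. Restricting k-NN to Delaunay-reachable cells would
be vacuous — a triangulation is connected — so plain k-NN is used. Windows
are clustered by K-means (k = 10, 10 restarts, seeded); CN integer labels
are arbitrary, so reporting keys on the annotation: each CN is annotated by
its highest-mean-composition metacluster (ties toward the cohort-wide rarer
population) and grouped as Epithelial-CN, MF_and_T-CN, Immune-suppressed-CN
(Treg-dominated) or T-CN; CNs dominated by the residual labels take the
largest grouped fraction.

Interaction/avoidance testing shuffles labels within each ROI (geometry
fixed, composition preserved), 1000 permutations by default; per pair
z = (observed − null mean)/null SD and empirical two-sided
p = (1 + #{|null − mean| ≥ |obs − mean|})/(1 + n_perm) — the +1 makes the
test slightly conservative but valid at any n_perm. The cohort-level
direction is the majority direction among ROIs significant at α = 0.05 (the
aggregation rule is configurable in principle — counting significant ROIs
was chosen over pooling counts because it is robust to ROI-size imbalance).
Voronoi maps mirror the points across the ROI box edges so every region is
bounded; clipped polygons tile the box exactly (area conservation is a
tested invariant).

## TIME subtyping (`imgene.subtyping`)

Consensus NMF on the ROI × metacluster fraction matrix (rows sum to 1):
rank 2, 50 runs with seeded random initializations, multiplicative updates
under the Frobenius objective (tol 1e−6, ≤ 500 inner iterations). A run
labels each ROI by its argmax basis coefficient; the consensus matrix is the
co-clustering fraction; final labels come from an average-linkage
hierarchical cut of (1 − consensus) at 2 clusters, with the mean silhouette
on consensus distances as the quality score. An input whose rows are all
identical is flagged degenerate (silhouette −1) instead of returning an
arbitrary split. Patient labels are the majority vote over their ROIs; ties
break toward the subtype with higher mean within-subtype consensus. Rank
selection beyond 2 is out of scope.

## ImGene predictor (`imgene.predictor`)

Feature blocks: ImFeatures = per-patient metacluster fractions (+ CN
abundances when the spatial stage ran); GeneFeatures = per-gene indicators
plus TMB, MATH and mutation count. Per block, features are ranked by the
absolute coefficients of an L2 logistic regression on standardized training
data and the top 10 kept (ties lexicographic). Each block's SVM is tuned by
leave-one-out CV over C ∈ {0.01, 0.1, 1, 10, 100}, kernel ∈ {linear, rbf},
gamma ∈ {0.001, 0.01, 0.1, 1} (the grid is a declared default — only the
tuned parameters are specified upstream), refitted on all training data, and
its decision scores min–max calibrated to [0, 1] on the training range.
Classification cutoffs are the scores maximizing validation accuracy (ties
to the lower cutoff); cutoffs never see test labels. The integration
logistic regression is fitted on the two calibrated training scores; its
intercept is overridable to the published 3.51 for formula-reproduction
checks. Evaluation reports rank-based ROC AUC plus F1 and accuracy at the
cutoff, for ImGene and both monomodal baselines, on a stratified 30%
validation split.

## Numerical and reproducibility choices

One `numpy.random.Generator` seeded from the single configured seed drives
every stochastic step, in documented order (clinical → mutations → cells);
derived seeds stay below 2³¹. K-means and NMF use fixed seeds with multiple
restarts. Degenerate inputs are handled explicitly: empty mutation tables
are valid; MATH is undefined (absent) below 3 VAFs or at zero median; ROIs
smaller than the window use all cells; fewer distinct windows than k reduces
k with a warning.

## Limitations

* The published real-cohort predictor metrics (AUC 0.86 training / 0.81
  external validation) are not reproducible without the undeposited data;
  the synthetic cohort yields its own, typically higher, separability.
* Gene-level effect recovery is power-limited at the published effect sizes
  and cohort size: a 55% vs 37% TP53 difference at 53 vs 204 patients gives
  a Fisher p ≈ 0.02 in expectation, which survives a q < 0.1 cut over a
  ~20-gene panel only in a minority of replicates. The acceptance suite
  asserts the ≥ 90%-of-seeds recovery bar for all four planted effects and
  the two gene-level assertions fail honestly; the composition effects
  (macrophage, Treg) recover in every seed.
* Driver significance modelling (MutSigCV/dNdScv-style), live actionability
  database queries, raw-image segmentation, survival analysis and external
  cohort comparisons are out of scope; the actionability and pathway tables
  ship as editable static configuration.
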