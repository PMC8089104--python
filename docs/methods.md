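# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## QC and normalization

The pipeline starts from a genes × cells expression matrix.  For full-length
protocols quantified on a TPM scale, integer count surrogates are recovered
as `round(TPM × read_length)` with `read_length = 43` bp by default and
halves rounded away from zero (the rounding convention of R's `round` for
positive halves, made explicit here).  Count recovery of this form assumes
library sizes are comparable across cells; it restores count-like
granularity for the hurdle test's detection component.

Per-cell composition fractions (mitochondrial, ribosomal, protein-coding,
non-coding) are count-weighted shares of the cell total, with ERCC spike-in
genes excluded from both numerator and denominator — spike-ins are not
cellular transcripts and would dilute every fraction.  Cell filters are
strict inequalities in the stated direction (a cell at exactly 40%
mitochondrial reads is kept): `pct_mito > 0.40`, `pct_ribo > 0.50`,
`pct_protein_coding < 0.50`, `n_genes < 200` each remove a cell, and genes
detected in fewer than 5 cells are dropped.  All five thresholds are plain
configuration values.  Zero-total cells have undefined fractions and always
fail the gene-count rule, so they can never reach normalization.

Log-normalization is `ln(1 + c / total × 1000)` (natural log, the dominant
single-cell convention when a procedure is named only as "log-normalize with
a scale factor").  Confounder regression fits, per gene, OLS of
log-expression on a per-cell covariate table (intercept always included) and
standardizes the residuals to mean 0, variance 1; constant genes become
all-zero rows rather than 0/0.  The covariates are the internally computed
mito/ribo/non-coding fractions plus any user-supplied numeric columns (sex
indicator, Y-chromosome fraction, cell-cycle scores); which columns enter is
a config choice because the encoding of these factors is not canonical.
Rank deficiency of the covariate design is an error that names the collinear
columns.  Manual exclusion lists (e.g. contaminating antigen-presenting
cells identified by marker expression) are supported as an explicit cell
list rather than a numeric rule.

## Clustering

Highly variable genes are ranked by observed variance minus a fitted
mean–variance trend (lowess by default, quadratic polynomial as an option —
the exact trend family is a free choice and both behave equivalently on the
planted fixtures; ties fall back to gene order so degenerate inputs are
deterministic).  PCA runs on the scaled matrix restricted to HVGs with 50
components by default; component signs are fixed by making the
largest-magnitude loading positive, and requests beyond the matrix's
numerical rank are truncated with a warning.

The neighbor graph uses **exact** Euclidean KNN (k = 10) rather than an
approximate search: approximation is a performance device with no
statistical content, and at the scales this package targets exactness is
free and removes an irreproducibility source.  Distance ties break by cell
index.  Directed neighbor lists are symmetrized into an undirected graph,
then edges are pruned by shared-nearest-neighbor Jaccard similarity with
threshold 1/15 (kept iff ≥ 1/15, the threshold read as the minimum
admissible similarity); surviving edges carry the Jaccard value as weight.
Louvain modularity optimization (resolution 2.4 by default, seeded) yields
the clusters.  Resolution is a plain parameter: the default suits the
tissue-atlas scale it was tuned for, while sanity checks on toy graphs (two
disconnected 20-cliques must give exactly two clusters) run at resolution
1.0 — at γ = 2.4 generalized modularity strictly prefers splitting a
20-clique, so the toy expectation is only meaningful near γ = 1.

## Hurdle differential expression

Each gene is tested one-cluster-vs-rest with a two-part hurdle test in the
MAST style: a Bernoulli likelihood-ratio statistic for equal detection rates
(closed form from the 2×2 detection table) and a Gaussian LR statistic
`N·ln(RSS₀/RSS₁)` for equal means of the positive log-expression values.
The component statistics and degrees of freedom are summed and referred to
χ².  Components collapse gracefully: no detection variation contributes 0
df; fewer than one positive cell in a group drops the continuous component;
a gene silent in both groups is untestable (p = 1, log₂FC = 0, flagged).
The implementation deliberately omits MAST's empirical-Bayes variance
shrinkage and cellular-detection-rate covariate — the test's structure, not
its regularization, is what downstream stages depend on, and null
calibration is verified directly (type-I error at α = 0.05 within
[0.04, 0.06] over 2000 simulated null genes).

log₂FC is the difference of group means of log-normalized expression (zeros
included) divided by ln 2 — an explicit, oracle-checkable estimator.  Marker
lists keep up-regulated genes with log₂FC > 0.25 and BH FDR < 0.01 (FDR
within each cluster's test family); the permissive selection feeding module
discovery keeps |log₂FC| > 0.1 with **raw** p < 0.1 (two-sided, unadjusted),
and the union over clusters is deduplicated in first-occurrence order.
Both boundaries are strict.

## Co-expression modules

Adjacency is unsigned Pearson: `a_ij = |r_ij|` across cells, diagonal 1,
with **no soft-threshold power** (equivalently power 1).  In sparse
single-cell data even genuinely co-regulated genes rarely correlate near 1,
so the classical power transform would compress the whole matrix toward 0.
Unsigned is the default because the direction of co-membership is not
informative for module discovery here; a signed variant `(1 + r)/2` is
available.  Constant genes are rejected by name before correlation.

The unsigned topological overlap is computed by matrix products
(`l = A·A` with a zeroed diagonal) and verified in the tests against a
triple-loop transcription of the definition.  Modules come from
agglomerative hierarchical clustering of `1 − TOM` with Ward's squared
linkage (ward.D2; SciPy's `ward` on a precomputed dissimilarity implements
the same Lance–Williams recursion, checked against a hand-coded oracle) cut
into a **fixed number** of modules — 100 by default, no dynamic tree cut.
Module ids are assigned by decreasing size with ties broken by earliest
gene, so labels are reproducible even though any fixed-cut labelling is
arbitrary.

Module scores min-max normalize each member gene across cells to [0, 1] and
average within the module; constant genes contribute 0 (they carry no
pattern, and the alternative is 0/0).  Scoring uses the log-normalized
matrix rather than the regression residuals — scores are meant to be read as
expression levels, and residuals are signed z-scores with no natural [0, 1]
anchor; the scaled matrix can be substituted by configuration.  The module
similarity graph links each module to its 5 most-correlated peers
(Pearson on score vectors, symmetrized union).

## Module prioritization

For each (module, factor) pair a Gaussian identity-link GLM of the score on
the one-hot factor gives `dev_model` = residual sum of squares and
`dev_null` = total sum of squares; the deviance ratio
`Δdev = (dev_null − dev_model)/dev_null` is the fraction of the module's
expression pattern the factor explains.  Gaussian is the one family under
which scores in [0, 1] need no transform and "deviance" reduces to RSS,
making Δdev exactly R² — which the tests exploit as an independent oracle.
Δdev is defined as 0 for constant scores (with a warning), lies in [0, 1],
is invariant to affine rescaling of the score, and can only grow when a
factor is refined.  Each factor is tested independently; no multiple-testing
correction is applied because the output is a ranking, not a test.  Modules
in which more than half the genes carry ribosomal or mitochondrial flags can
be flagged as housekeeping and excluded from rank numbering while staying in
the table.

## TCR rearrangement classification

Clone records (cell, chain ∈ {TRA, TRB, TRG, TRD}, CDR3 nucleotide and
amino-acid sequence, read count) are filtered to count **strictly** greater
than 5 to suppress false-positive clone calls; the threshold applies to
reads (full-length protocols carry no UMIs).  Within each (cell, chain) the
highest-count clone survives, ties broken by lexicographically smallest CDR3
nucleotide sequence so results never depend on row order.  The per-cell
category is determined by which loci survive: both an αβ chain and a γδ
chain present gives `TRA_B_G_D`; only αβ gives `TRA_B`; only γδ gives
`TRG_D`; nothing gives `none`.  This partitions all 16 chain subsets with no
gaps.  Clone identity for frequency and overlap reports is (chain, CDR3
nucleotide); amino-acid grouping is an option.

## Cross-dataset comparison

The overlap of two per-cluster up-regulated DEG lists is tested with the
upper-tail hypergeometric probability P(X ≥ k) after intersecting both
lists with a shared background — genes detected in at least 5 cells in
*both* datasets.  The inclusive tail (≥ k, not > k) matches the standard
overlap-test convention and is verified against exhaustive enumeration.
Cluster similarity is the Spearman correlation of per-cluster mean
log-normalized expression over the union of each cluster's top-100 DEGs
(fewer when fewer are significant); rank correlation makes the choice of
expression scale nearly immaterial.

## Synthetic data

The generator emulates exactly the statistical structure the stages assume,
with a lognormal-Poisson count model: per-gene baselines `N(1, 0.8)` on the
log scale (mean counts of a few per gene, typical of downsampled full-length
data), subset-specific log₂ effects for planted DE genes, and planted
co-expression modules driven by a latent activity
`effect × (level indicator + N(0, 0.5))` shared by all member genes —
the Gaussian term induces within-module correlation beyond what the factor
explains, as real regulons show.  Confounders (strength 0.5 by default) load
on deterministic gene blocks: mitochondrial, ribosomal and non-coding flags
occupy fixed leading index ranges, cell-cycle loadings the trailing 5% of
genes, and Y-chromosome genes are zeroed in cells of female donors.
Dropout is Bernoulli thinning at rate 0.1 by default — modest, as expected
for full-length chemistry at reasonable depth.  Per-cell covariates in the
returned truth are recomputed from the final matrix, so they are consistent
with what QC will measure.

Clone tables plant a category per cell, partition each category's cells into
clonal families with shifted-geometric sizes (support ≥ 1), and give true
clones counts ≥ 6 while noise clones (and every clone of a `none` cell) stay
at counts 1–5, so the count filter is exercised on both sides; secondary
clones with strictly lower counts exercise dominant-clone selection.  The QC
fixture plants known violators of each cell rule (including one cell
violating two rules at once), one gene detected in exactly 4 kept cells and
one in exactly 5.

What the generator does **not** emulate: transcript-length bias, batch and
plate effects, ambient contamination, doublets, realistic TCR locus
sequence, or biologically structured gene programs beyond the planted ones.
Tests passing on this data therefore demonstrate the correctness of the
computations and the recoverability of planted structure — not robustness to
every artefact of real tissue data.

## Problem sizes and determinism

The test and verification workloads are sized for a single CPU at desk
scale: 500 cells × 600 genes for module recovery and prioritization (20
independent simulations for the prioritization rate), 2000 genes × 300
cells for null calibration, 200 points for the KNN oracle, and ≤ 30 genes
for the brute-force TOM and linkage oracles.  Every stochastic step takes an
explicit seed; the pipeline manifest records the config hash and seed, and a
rerun with the same inputs reproduces byte-identical tables.

## Known limitations

- The hurdle test's χ² reference is asymptotic; in very small groups
  (tens of cells) it can run slightly liberal.  No small-sample correction
  is applied.
- The lowess HVG trend is not robust to a variance outlier isolated in mean
  space (a single gene far outside the mean range fits its own trend point);
  such genes are better handled by the polynomial trend option.
- Fixed-count tree cutting guarantees exactly `n_modules` modules even when
  the data support fewer distinct programs; downstream Δdev ranking, not the
  cut, is what separates signal from filler modules.
- Louvain at high resolution fragments cliques by design; interpret the
  default 2.4 as an atlas-scale choice, not a universal constant.
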