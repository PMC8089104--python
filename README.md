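# scmodules

Tools for analysing full-length (Smart-seq2-style) single-cell RNA-seq of
tissue lymphocytes — built around the workflow used to map human innate
lymphoid cell (ILC) heterogeneity across tissues: quality control and
normalization of per-cell expression, graph-based clustering, hurdle-model
differential expression, gene co-expression **module** discovery on a
power-free topological overlap matrix, module prioritization by a GLM
deviance ratio, and classification of TCR V(D)J rearrangements from clone
tables.  A synthetic-data generator with planted ground truth makes every
stage verifiable at desk scale.

## What it computes

**QC / normalization.** TPM-scale values are converted to count surrogates
(`round(TPM × read length)`, 43 bp default).  Cells are removed when
mitochondrial reads exceed 40% of the library, ribosomal reads exceed 50%,
protein-coding reads fall below 50%, or fewer than 200 genes are detected;
genes seen in fewer than 5 cells are dropped.  Counts are log-normalized
(`ln(1 + c/total × 1000)`) and z-scored after OLS regression of per-cell
confounders (mitochondrial/ribosomal/non-coding fractions, sex, cell-cycle
scores).

**Clustering.** Highly variable genes by excess variance over a
mean–variance trend, PCA (50 PCs), exact k=10 nearest-neighbor graph,
shared-nearest-neighbor pruning at Jaccard ≥ 1/15, Louvain communities at
resolution 2.4.

**Differential expression.** A two-part hurdle likelihood-ratio test per
gene (logistic detection component + Gaussian component on positive
log-expression; summed LR statistics against χ²).  Markers use
log₂FC > 0.25 and BH FDR < 0.01; a permissive union (|log₂FC| > 0.1,
raw p < 0.1) selects genes for module discovery.

**Co-expression modules.** Unsigned adjacency `a_ij = |r_ij|` with the
soft-threshold power deliberately skipped (single-cell correlations rarely
approach 1, so powering flattens the matrix), topological overlap

```
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = Σ_u a_iu a_uj
```

Ward.D2 hierarchical clustering of `1 − TOM` cut into a fixed 100 modules,
per-cell module scores in [0, 1] (mean of min-max-normalized member genes),
and a 5-NN module similarity graph.

**Module prioritization.** Per (module, metadata factor), a Gaussian GLM of
the score on the factor gives `Δdev = (dev_null − dev_model)/dev_null` —
the fraction of a module's expression pattern the factor explains (equal to
R² in this setting).  Modules dominated by ribosomal/mitochondrial genes can
be flagged out of the ranking.

**TCR rearrangements.** Clone tables are filtered to read count > 5, the
dominant clone per (cell, chain) kept, and each cell labelled
`none` / `TRA_B` / `TRG_D` / `TRA_B_G_D` from its surviving chain set, with
clone-frequency and cross-population clonal-overlap reports.

**Cross-dataset comparison.** Hypergeometric upper-tail tests of per-cluster
DEG overlap against a background of genes detected in ≥ 5 cells in both
datasets, and Spearman correlation of cluster means over the union of
top-100 DEGs.

## Worked example

```bash
scmodules simulate --out sim --seed 5 --n-cells 200 --n-genes 400 --n-planted-modules 5
scmodules all --matrix sim/matrix --metadata sim/metadata.csv \
          --clones sim/clones.tsv --out run --counts-input
```

which prints the stage artifacts:

```json
{
  "qc": "qc_table.csv",
  "normalize": "normalized.mtx",
  "regress": "scaled.mtx",
  "cluster": "clusters.csv",
  "de": "de_table.csv",
  "permissive": "permissive_genes.tsv",
  "modules": "module_assignment.tsv",
  "priority": "module_priority.csv",
  "tcr": "tcr_calls.csv"
}
```

`run/module_priority.csv` ranks every module against every metadata factor
by Δdev; the planted tissue-driven modules surface at rank 1.  The same
stages are available individually (`scmodules qc`, `cluster`, `de`,
`modules`, `prioritize`, `tcr`, `compare`), each reading the previous
stage's on-disk artifacts, e.g.

```bash
scmodules prioritize --scores run/module_scores.tsv --metadata sim/metadata.csv \
          --factors tissue,subset --out prio
 module_id factor  dev_null  dev_model  delta_dev  rank  housekeeping_flag
        60 subset  7.999658   7.603875   0.049475   1.0              False
        45 subset 10.206842   9.811959   0.038688   2.0              False
```

(`delta_dev` is the share of that module's score variance explained by the
factor; on this unstructured background it stays near 0, while a genuinely
tissue-driven module reaches values near 1.)

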