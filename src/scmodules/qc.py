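"""Cell/gene quality control, count recovery, log-normalization and
confounder-regression scaling for full-length (Smart-seq2-style) scRNA-seq.

The pipeline starts from a TPM-scale expression matrix. Read counts are
recovered by multiplying TPMs by the read length (default 43 bp) and rounding.
Cells are removed when the mitochondrial read fraction exceeds 40%, the
ribosomal fraction exceeds 50%, the protein-coding fraction falls below 50%,
or fewer than 200 genes are detected; genes detected in fewer than five cells
are dropped.  Counts are then log-normalized with a scale factor of 1000 and
z-scored after ordinary-least-squares regression of per-cell confounders
(mitochondrial / ribosomal / non-coding fractions, sex, cell-cycle scores).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "make_gene_annotation",
    "recover_counts",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "lognormalize",
    "regress_confounders",
]

#: columns every gene-annotation table must carry
ANNOTATION_COLUMNS = ("symbol", "biotype", "mito", "ribo", "y_chr", "spikein")

BIOTYPES = ("protein_coding", "non_coding", "other")


def make_gene_annotation(
    gene_ids,
    symbols=None,
    biotype="protein_coding",
    mito=(),
    ribo=(),
    y_chr=(),
    spikein=(),
) -> pd.DataFrame:
    """Assemble a gene-annotation table.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (index of the result).
    biotype
        Either one biotype for all genes or a per-gene sequence; values must
        be drawn from ``{"protein_coding", "non_coding", "other"}``.
    mito, ribo, y_chr, spikein
        Collections of gene ids carrying the respective flag.
    """
    index = pd.Index(gene_ids, name="gene_id")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if isinstance(biotype, str):
        biotype = [biotype] * len(index)
    biotype = pd.Series(list(biotype), index=index, name="biotype")
    bad = set(biotype.unique()) - set(BIOTYPES)
    if bad:
        raise ValueError(f"unknown biotypes: {sorted(bad)}")
    if symbols is None:
        symbols = list(index)
    ann = pd.DataFrame(
        {
            "symbol": list(symbols),
            "biotype": biotype,
            "mito": index.isin(set(mito)),
            "ribo": index.isin(set(ribo)),
            "y_chr": index.isin(set(y_chr)),
            "spikein": index.isin(set(spikein)),
        },
        index=index,
    )
    return ann


@dataclass
class CountMatrix:
    """Genes x cells expression matrix with gene annotations.

    ``values`` may hold TPM-scale reals or recovered integer counts; entries
    are never negative.  Rows are indexed by ``genes`` (an annotation table
    whose index is the gene id), columns by ``cells``.
    """

    values: np.ndarray
    genes: pd.DataFrame
    cells: pd.Index
    #: signed matrices (regression residuals) may hold negative entries
    signed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not isinstance(self.cells, pd.Index):
            self.cells = pd.Index(self.cells, name="cell_id")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        n_genes, n_cells = self.values.shape
        if len(self.genes) != n_genes or len(self.cells) != n_cells:
            raise ValueError(
                f"axis mismatch: values {self.values.shape}, "
                f"{len(self.genes)} genes, {len(self.cells)} cells"
            )
        if self.genes.index.has_duplicates or self.cells.has_duplicates:
            raise ValueError("gene and cell identifiers must be unique")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene annotation lacks columns: {missing}")
        if not self.signed and np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def subset(self, gene_ids=None, cell_ids=None) -> "CountMatrix":
        """Return a new matrix restricted to the given genes and/or cells."""
        gi = slice(None) if gene_ids is None else self.gene_ids.get_indexer(gene_ids)
        ci = slice(None) if cell_ids is None else self.cells.get_indexer(cell_ids)
        if gene_ids is not None and np.any(np.asarray(gi) < 0):
            raise KeyError("unknown gene ids in subset")
        if cell_ids is not None and np.any(np.asarray(ci) < 0):
            raise KeyError("unknown cell ids in subset")
        return CountMatrix(
            self.values[gi][:, ci] if gene_ids is not None else self.values[:, ci],
            self.genes.iloc[gi] if gene_ids is not None else self.genes,
            self.cells[ci] if cell_ids is not None else self.cells,
            signed=self.signed,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cell and gene filter thresholds.

    Cells are removed when a fraction lies strictly beyond its bound
    (``pct_mito > max_pct_mito`` etc.); genes are kept when detected in at
    least ``min_cells_per_gene`` cells.
    """

    max_pct_mito: float = 0.40
    max_pct_ribo: float = 0.50
    min_pct_protein_coding: float = 0.50
    min_n_genes: int = 200
    min_cells_per_gene: int = 5

    def __post_init__(self):
        for name in ("max_pct_mito", "max_pct_ribo", "min_pct_protein_coding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_n_genes < 0 or self.min_cells_per_gene < 0:
            raise ValueError("integer minimums must be >= 0")


def recover_counts(tpm_matrix: CountMatrix, read_length: int = 43) -> CountMatrix:
    """Turn TPM-scale values into integer count surrogates.

    Each entry becomes ``round(value * read_length)`` with halves rounded
    away from zero; zeros stay zero.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    v = tpm_matrix.values * float(read_length)
    counts = np.floor(v + 0.5)  # half away from zero (inputs are >= 0)
    return replace(tpm_matrix, values=counts)


def compute_qc_metrics(counts: CountMatrix) -> pd.DataFrame:
    """Per-cell QC table: count-weighted composition fractions and gene counts.

    ERCC spike-in genes are excluded from both the totals and the flagged
    fractions.  Cells with zero total counts get NaN fractions and are
    guaranteed to fall to the ``min_n_genes`` rule downstream.
    """
    cellular = ~counts.genes["spikein"].to_numpy()
    v = counts.values[cellular]
    ann = counts.genes.loc[cellular]
    total = v.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        def frac(mask):
            return np.where(total > 0, v[mask].sum(axis=0) / total, np.nan)

        qc = pd.DataFrame(
            {
                "pct_mito": frac(ann["mito"].to_numpy()),
                "pct_ribo": frac(ann["ribo"].to_numpy()),
                "pct_protein_coding": frac((ann["biotype"] == "protein_coding").to_numpy()),
                "pct_noncoding": frac((ann["biotype"] == "non_coding").to_numpy()),
                "n_genes": (v > 0).sum(axis=0),
                "total_counts": total,
            },
            index=counts.cells,
        )
    return qc


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Index:
    """Return the cell ids passing all four cell-level rules, order preserved.

    A cell is removed iff ``pct_mito > max_pct_mito`` OR
    ``pct_ribo > max_pct_ribo`` OR ``pct_protein_coding < min_pct_protein_coding``
    OR ``n_genes < min_n_genes`` (all strict, following the thresholds'
    "above"/"below" reading).  NaN fractions (zero-count cells) never pass:
    such cells always fail the gene-count rule.
    """
    t = thresholds
    bad = (
        (qc["pct_mito"] > t.max_pct_mito).fillna(False)
        | (qc["pct_ribo"] > t.max_pct_ribo).fillna(False)
        | (qc["pct_protein_coding"] < t.min_pct_protein_coding).fillna(False)
        | (qc["n_genes"] < t.min_n_genes)
    )
    return qc.index[~bad.to_numpy()]


def filter_genes(counts: CountMatrix, min_cells: int = 5) -> pd.Index:
    """Return gene ids detected (value > 0) in at least ``min_cells`` cells.

    Spike-in genes are dropped regardless of detection."""
    detected = (counts.values > 0).sum(axis=1)
    keep = (detected >= min_cells) & ~counts.genes["spikein"].to_numpy()
    return counts.gene_ids[keep]


def lognormalize(counts: CountMatrix, scale_factor: float = 1000.0) -> CountMatrix:
    """Library-size log-normalization: ``ln(1 + count / cell_total * scale)``.

    Zero-total cells must have been filtered out beforehand."""
    total = counts.values.sum(axis=0)
    if np.any(total <= 0):
        bad = list(counts.cells[total <= 0])
        raise ValueError(f"zero-total cells present (filter first): {bad}")
    norm = np.log1p(counts.values / total * scale_factor)
    return replace(counts, values=norm)


def _collinear_columns(design: np.ndarray, names) -> list:
    """Greedy scan flagging columns that add nothing to the design's rank."""
    bad, kept = [], np.empty((design.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    return bad


def regress_confounders(norm: CountMatrix, covariates: pd.DataFrame | None) -> CountMatrix:
    """Regress per-cell confounders out of each gene and z-score the residuals.

    Fits, per gene, an OLS model of log-expression on the covariate table
    (intercept always included) and standardizes the residuals to mean 0 /
    variance 1.  Constant genes come back as all-zero rows.  With
    ``covariates=None`` this reduces to a per-gene z-score.
    """
    n_genes, n_cells = norm.shape
    if covariates is None or covariates.shape[1] == 0:
        design = np.ones((n_cells, 1))
        names = ["intercept"]
    else:
        cov = covariates.loc[norm.cells]
        if cov.isna().to_numpy().any() or not np.all(np.isfinite(cov.to_numpy(float))):
            raise ValueError("covariates must be complete and finite")
        design = np.column_stack([np.ones(n_cells), cov.to_numpy(float)])
        names = ["intercept"] + list(cov.columns)
    if n_cells < design.shape[1] + 2:
        raise ValueError("need at least 2 more cells than covariates")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate table; collinear columns: {bad}")

    coef, *_ = np.linalg.lstsq(design, norm.values.T, rcond=None)
    resid = norm.values - (design @ coef).T
    sd = resid.std(axis=1)
    const = sd < 1e-12
    sd[const] = 1.0
    scaled = (resid - resid.mean(axis=1, keepdims=True)) / sd[:, None]
    scaled[const] = 0.0
    return replace(norm, values=scaled, signed=True)
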