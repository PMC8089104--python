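"""Synthetic single-cell fixtures with planted ground truth.

Every downstream stage of the pipeline assumes some statistical structure:
co-expressed gene modules tied to metadata factors, subset-specific
differential expression, per-cell composition confounders, zero inflation,
and clonally expanded TCR rearrangements.  This module generates desk-scale
datasets carrying all of that structure by construction, so each stage can be
verified against a known truth without downloading anything.

Counts follow a lognormal-Poisson model: the log mean of each gene in each
cell is a gene baseline plus subset-program effects, plus module-factor
activity times the module effect, plus confounder loadings; counts are
Poisson samples of the exponentiated log mean, optionally thinned by a
Bernoulli dropout mask.  This reproduces the overdispersion and zero
inflation the hurdle DE test assumes without extra parameters.

Gene annotation flags occupy fixed index ranges (mitochondrial genes first,
then ribosomal, Y-chromosome, non-coding), so QC rules are testable without
a real annotation; cell-cycle loadings sit on the trailing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .qc import CountMatrix, make_gene_annotation
from .tcr import CATEGORIES, CLONE_COLUMNS

__all__ = [
    "PlantedModule",
    "SyntheticConfig",
    "SyntheticTruth",
    "synthetic_annotation",
    "generate_expression",
    "generate_clone_table",
    "generate_qc_fixture",
]

# flag fractions for the deterministic annotation layout
_FLAG_FRACS = {"mito": 0.02, "ribo": 0.05, "y_chr": 0.01, "non_coding": 0.10}
_CC_FRAC = 0.05  # trailing genes carrying cell-cycle loadings


@dataclass(frozen=True)
class PlantedModule:
    """A co-expression module planted on a gene-index set.

    ``factor``/``level`` optionally tie the module's latent activity to a
    metadata factor (e.g. tissue); ``effect`` is the mean log-expression
    shift per unit of activity.
    """

    genes: tuple
    effect: float = 2.0
    factor: str | None = None
    level: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_cells: int = 500
    n_genes: int = 600
    n_tissues: int = 3
    n_subsets: int = 3
    n_donors: int = 4
    planted_modules: tuple = ()
    de_genes: tuple = ()  # (gene index, subset index, log2 effect)
    dropout_rate: float = 0.1
    confounder_strength: float = 0.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.8
    module_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_tissues, self.n_subsets, self.n_donors) < 1:
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate={self.dropout_rate} outside [0, 1]")
        if self.confounder_strength < 0:
            raise ValueError("confounder_strength must be non-negative")
        seen = set()
        for m in self.planted_modules:
            genes = set(m.genes)
            if genes & seen:
                raise ValueError("planted module gene sets must be pairwise disjoint")
            seen |= genes
            if any(g < 0 or g >= self.n_genes for g in genes):
                raise ValueError("module gene index outside matrix")
            if m.factor is not None and m.factor not in ("tissue", "subset", "donor"):
                raise ValueError(f"unknown driving factor {m.factor!r}")
        for g, s, _ in self.de_genes:
            if g < 0 or g >= self.n_genes:
                raise ValueError("DE gene index outside matrix")
            if s < 0 or s >= self.n_subsets:
                raise ValueError("DE subset index outside range")


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator run."""

    module_assignment: pd.Series  # gene_id -> module index (NaN if unplanted)
    de_table: pd.DataFrame  # planted (gene, subset, log2_effect)
    cell_labels: pd.DataFrame  # tissue/subset/donor per cell
    covariates: pd.DataFrame  # per-cell fractions, sex, cell-cycle score
    clone_truth: pd.Series | None = None
    clone_families: list = field(default_factory=list)


def _gene_ids(n):
    return [f"g{i:05d}" for i in range(n)]


def _cell_ids(n):
    return [f"cell{i:05d}" for i in range(n)]


def synthetic_annotation(n_genes: int) -> pd.DataFrame:
    """Deterministic annotation: flags assigned to fixed leading index ranges."""
    ids = _gene_ids(n_genes)
    n_mito = max(1, round(_FLAG_FRACS["mito"] * n_genes))
    n_ribo = max(1, round(_FLAG_FRACS["ribo"] * n_genes))
    n_y = max(1, round(_FLAG_FRACS["y_chr"] * n_genes))
    n_nc = max(1, round(_FLAG_FRACS["non_coding"] * n_genes))
    mito = ids[:n_mito]
    ribo = ids[n_mito : n_mito + n_ribo]
    y = ids[n_mito + n_ribo : n_mito + n_ribo + n_y]
    nc_start = n_mito + n_ribo + n_y
    biotype = ["protein_coding"] * n_genes
    for i in range(nc_start, min(nc_start + n_nc, n_genes)):
        biotype[i] = "non_coding"
    return make_gene_annotation(ids, biotype=biotype, mito=mito, ribo=ribo, y_chr=y)


def generate_expression(config: SyntheticConfig):
    """Sample a counts matrix, cell metadata and the planted truth.

    Returns ``(counts, metadata, truth)``.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_c = config.n_genes, config.n_cells
    ann = synthetic_annotation(n_g)
    gene_ids = ann.index
    cells = pd.Index(_cell_ids(n_c), name="cell_id")

    tissue = rng.integers(0, config.n_tissues, n_c)
    subset = rng.integers(0, config.n_subsets, n_c)
    donor = rng.integers(0, config.n_donors, n_c)
    donor_sex = rng.choice(["M", "F"], size=config.n_donors)
    sex = donor_sex[donor]
    labels = pd.DataFrame(
        {
            "tissue": [f"tissue{t}" for t in tissue],
            "subset": [f"subset{s}" for s in subset],
            "donor": [f"donor{d}" for d in donor],
        },
        index=cells,
    )

    logmu = np.tile(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_g)[:, None],
        (1, n_c),
    )

    de_rows = []
    for g, s, log2fc in config.de_genes:
        logmu[g, subset == s] += log2fc * np.log(2.0)
        de_rows.append((gene_ids[g], f"subset{s}", log2fc))
    de_table = pd.DataFrame(de_rows, columns=["gene", "subset", "log2_effect"])

    module_assignment = pd.Series(np.nan, index=gene_ids, name="module")
    for mi, mod in enumerate(config.planted_modules):
        if mod.factor is None:
            indicator = np.zeros(n_c)
        else:
            indicator = (labels[mod.factor].to_numpy() == mod.level).astype(float)
        activity = indicator + rng.normal(0.0, config.module_noise_sd, n_c)
        gi = np.fromiter(mod.genes, dtype=int)
        logmu[gi] += mod.effect * activity
        module_assignment.iloc[gi] = mi

    s = config.confounder_strength
    cc_genes = np.arange(max(0, n_g - max(1, round(_CC_FRAC * n_g))), n_g)
    cc_score = rng.normal(0.0, 1.0, n_c)
    if s > 0:
        for flag in ("mito", "ribo"):
            load = rng.normal(0.0, 1.0, n_c)
            logmu[ann[flag].to_numpy()] += s * 0.5 * load
        nc_mask = (ann["biotype"] == "non_coding").to_numpy()
        logmu[nc_mask] += s * 0.5 * rng.normal(0.0, 1.0, n_c)
        logmu[cc_genes] += s * 0.5 * cc_score

    counts = rng.poisson(np.exp(np.clip(logmu, None, 12.0))).astype(float)
    counts[np.ix_(ann["y_chr"].to_numpy().nonzero()[0], (sex == "F").nonzero()[0])] = 0.0
    if config.dropout_rate > 0:
        counts *= rng.random((n_g, n_c)) >= config.dropout_rate

    matrix = CountMatrix(counts, ann, cells)

    total = counts.sum(axis=0)
    total_safe = np.where(total > 0, total, 1.0)
    covariates = pd.DataFrame(
        {
            "pct_mito": counts[ann["mito"].to_numpy()].sum(axis=0) / total_safe,
            "pct_ribo": counts[ann["ribo"].to_numpy()].sum(axis=0) / total_safe,
            "pct_noncoding": counts[(ann["biotype"] == "non_coding").to_numpy()].sum(axis=0)
            / total_safe,
            "sex_male": (sex == "M").astype(float),
            "cc_score": cc_score,
        },
        index=cells,
    )
    metadata = labels.join(covariates)
    truth = SyntheticTruth(
        module_assignment=module_assignment,
        de_table=de_table,
        cell_labels=labels,
        covariates=covariates,
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# clone tables


def _random_cdr3(rng, used: set, length: int = 21) -> str:
    while True:
        nt = "".join(rng.choice(list("ACGT"), size=length))
        if nt not in used:
            used.add(nt)
            return nt


def _chain_sets(rng, category):
    ab = [("TRA",), ("TRB",), ("TRA", "TRB")]
    gd = [("TRG",), ("TRD",), ("TRG", "TRD")]
    p = [0.3, 0.3, 0.4]
    if category == "TRA_B":
        return ab[rng.choice(3, p=p)]
    if category == "TRG_D":
        return gd[rng.choice(3, p=p)]
    if category == "TRA_B_G_D":
        return tuple(sorted(set(ab[rng.choice(3, p=p)]) | set(gd[rng.choice(3, p=p)])))
    return ()


def generate_clone_table(
    n_cells: int,
    category_probs: dict,
    clone_size_p: float = 0.5,
    seed: int = 0,
    noise_clone_rate: float = 0.3,
    secondary_clone_rate: float = 0.2,
):
    """Sample a MiXCR-style clone table with planted rearrangement categories.

    Cells are assigned a category from ``category_probs``; cells sharing a
    clonal family (family sizes are shifted-geometric with parameter
    ``clone_size_p``, support >= 1) share CDR3 sequences.  True clones carry
    read counts > 5; each cell may additionally emit sub-threshold noise
    clones (count 1-5, removed by the filter) and lower-count secondary
    clones on an already-rearranged chain (exercising dominant-clone
    selection).  Returns ``(clone_table, truth)`` with truth holding the
    per-cell category and the planted (chain, cdr3_nt, cells) families.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    cats = list(category_probs)
    bad = set(cats) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    probs = np.array([category_probs[c] for c in cats], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("category probabilities must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    cells = _cell_ids(n_cells)
    assigned = [cats[i] for i in rng.choice(len(cats), size=n_cells, p=probs)]
    truth_cat = pd.Series(assigned, index=pd.Index(cells, name="cell_id"), name="category")

    rows, used_cdr3, families = [], set(), []
    for category in ("TRA_B", "TRG_D", "TRA_B_G_D"):
        members = [c for c, a in zip(cells, assigned) if a == category]
        pos = 0
        while pos < len(members):
            size = int(rng.geometric(clone_size_p))
            family = members[pos : pos + size]
            pos += size
            chains = _chain_sets(rng, category)
            for chain in chains:
                nt = _random_cdr3(rng, used_cdr3)
                aa = str(Seq(nt).translate())
                families.append({"chain": chain, "cdr3_nt": nt, "cells": list(family)})
                for cell in family:
                    count = int(6 + rng.geometric(0.3) - 1)
                    rows.append((cell, chain, nt, aa, count))
                    if rng.random() < secondary_clone_rate and count > 6:
                        nt2 = _random_cdr3(rng, used_cdr3)
                        rows.append(
                            (cell, chain, nt2, str(Seq(nt2).translate()),
                             int(rng.integers(6, count)))
                        )
    # sub-threshold noise on every cell, including "none" cells
    for cell in cells:
        if rng.random() < noise_clone_rate:
            chain = ("TRA", "TRB", "TRG", "TRD")[rng.choice(4)]
            nt = _random_cdr3(rng, used_cdr3)
            rows.append((cell, chain, nt, str(Seq(nt).translate()), int(rng.integers(1, 6))))

    table = pd.DataFrame(rows, columns=CLONE_COLUMNS)
    truth = SyntheticTruth(
        module_assignment=pd.Series(dtype=float),
        de_table=pd.DataFrame(),
        cell_labels=pd.DataFrame(index=truth_cat.index),
        covariates=pd.DataFrame(index=truth_cat.index),
        clone_truth=truth_cat,
        clone_families=families,
    )
    return table, truth


# ---------------------------------------------------------------------------
# QC fixture


def generate_qc_fixture(seed: int = 0):
    """A counts matrix with cells deliberately violating each QC rule.

    Returns ``(matrix, truth)`` where truth maps each rule to the planted
    violator ids: 5 high-mito cells, 3 high-ribo, 3 low-protein-coding, 4
    low-gene-count, 1 cell violating the mito and ribo rules simultaneously,
    one gene detected in exactly 4 kept cells (removed) and one in exactly 5
    (kept).
    """
    rng = np.random.default_rng(seed)
    n_genes = 300
    ids = _gene_ids(n_genes)
    mito, ribo, y = ids[:6], ids[6:18], ids[18:21]
    biotype = ["protein_coding"] * n_genes
    for i in range(21, 51):
        biotype[i] = "non_coding"
    ann = make_gene_annotation(ids, biotype=biotype, mito=mito, ribo=ribo, y_chr=y)

    cols, names = [], []

    def add_cell(name, counts):
        cols.append(counts)
        names.append(name)

    # 40 healthy cells: dense over genes 0..297, genes 298/299 reserved
    for i in range(40):
        c = rng.integers(5, 15, n_genes).astype(float)
        c[298:] = 0.0
        add_cell(f"ok{i:02d}", c)
    # 5 high-mito cells (~60% mito)
    for i in range(5):
        c = rng.integers(5, 15, n_genes).astype(float)
        c[298:] = 0.0
        c[:6] = round(0.6 * c[6:].sum() / 0.4 / 6)
        add_cell(f"himito{i}", c)
    # 3 high-ribo cells (~60% ribo)
    for i in range(3):
        c = rng.integers(5, 15, n_genes).astype(float)
        c[298:] = 0.0
        c[6:18] = round(0.6 * (c[:6].sum() + c[18:].sum()) / 0.4 / 12)
        add_cell(f"hiribo{i}", c)
    # 3 low-protein-coding cells (~60% non-coding counts)
    for i in range(3):
        c = rng.integers(5, 15, n_genes).astype(float)
        c[298:] = 0.0
        other = c[:21].sum() + c[51:].sum()
        c[21:51] = round(0.6 * other / 0.4 / 30)
        add_cell(f"lowpc{i}", c)
    # 4 cells detecting only 150 genes
    for i in range(4):
        c = np.zeros(n_genes)
        c[:150] = rng.integers(5, 15, 150)
        add_cell(f"lowgenes{i}", c)
    # 1 cell violating mito AND ribo rules (protein-coding fraction stays high)
    c = np.zeros(n_genes)
    c[51:298] = 1.0
    rest = c.sum()
    c[:6] = round(0.45 * rest / 0.04 / 6)
    c[6:18] = round(0.51 * rest / 0.04 / 12)
    add_cell("double0", c)

    values = np.column_stack(cols)
    # gene 298: detected in exactly 4 healthy cells; gene 299: exactly 5
    values[298, :4] = 7.0
    values[299, :5] = 7.0

    matrix = CountMatrix(values, ann, pd.Index(names, name="cell_id"))
    truth = {
        "high_mito": {f"himito{i}" for i in range(5)} | {"double0"},
        "high_ribo": {f"hiribo{i}" for i in range(3)} | {"double0"},
        "low_protein_coding": {f"lowpc{i}" for i in range(3)},
        "low_n_genes": {f"lowgenes{i}" for i in range(4)},
        "removed_cells": (
            {f"himito{i}" for i in range(5)}
            | {f"hiribo{i}" for i in range(3)}
            | {f"lowpc{i}" for i in range(3)}
            | {f"lowgenes{i}" for i in range(4)}
            | {"double0"}
        ),
        "removed_genes": {"g00298"},
        "kept_boundary_gene": "g00299",
    }
    return matrix, truth
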