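"""Cross-dataset cluster comparison by DEG overlap and rank correlation.

Two clusterings of independent datasets are compared in two ways: a
hypergeometric (phyper-style) upper-tail test of the overlap between each
pair of per-cluster up-regulated DEG lists, restricted to a shared background
of genes detected in at least 5 cells in both datasets; and a Spearman
correlation matrix of per-cluster mean expression over the union of each
cluster's top DEGs (up to 100 per cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import CountMatrix

__all__ = [
    "OverlapTestResult",
    "deg_overlap_test",
    "build_background",
    "cluster_correlation",
]


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap of two gene lists within a background universe."""

    k: int  # overlap size
    K: int  # |list_a ∩ background|
    n: int  # |list_b ∩ background|
    N: int  # background size
    p_value: float


def deg_overlap_test(list_a, list_b, background) -> OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists.

    Both lists are intersected with the background first; the p-value is
    P(X >= k) for X ~ Hypergeometric(N, K, n), i.e. the probability of
    drawing at least the observed overlap when sampling |list_b| genes from
    the background.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    a = set(list_a) & background
    b = set(list_b) & background
    k = len(a & b)
    K, n, N = len(a), len(b), len(background)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(k=k, K=K, n=n, N=N, p_value=min(p, 1.0))


def build_background(
    matrix_a: CountMatrix, matrix_b: CountMatrix, min_cells: int = 5
) -> pd.Index:
    """Genes detected in at least ``min_cells`` cells in both datasets."""
    shared = matrix_a.gene_ids.intersection(matrix_b.gene_ids)
    if len(shared) == 0:
        raise ValueError("datasets share no gene identifiers")

    def detected(m: CountMatrix) -> pd.Index:
        n = (m.values > 0).sum(axis=1)
        return m.gene_ids[n >= min_cells]

    keep = detected(matrix_a).intersection(detected(matrix_b))
    return shared.intersection(keep)


def _cluster_means(norm: CountMatrix, labels: pd.Series, panel: pd.Index) -> pd.DataFrame:
    sub = norm.subset(gene_ids=panel)
    labels = labels.loc[norm.cells]
    out = {}
    for c in sorted(pd.unique(labels)):
        out[c] = sub.values[:, (labels == c).to_numpy()].mean(axis=1)
    return pd.DataFrame(out, index=panel)


def cluster_correlation(
    norm_a: CountMatrix,
    labels_a: pd.Series,
    norm_b: CountMatrix,
    labels_b: pd.Series,
    degs_a: dict,
    degs_b: dict,
    top_n: int = 100,
) -> pd.DataFrame:
    """Spearman correlation of cluster mean expression over top DEGs.

    ``degs_a`` / ``degs_b`` map each cluster to its DEG list ordered by
    significance; the panel is the union over clusters of the top ``top_n``
    genes from both datasets, intersected with the genes present in both
    matrices.  Returns a clusters_a x clusters_b correlation matrix.
    """
    shared = norm_a.gene_ids.intersection(norm_b.gene_ids)
    panel = []
    for degs in (degs_a, degs_b):
        for genes in degs.values():
            panel.extend(genes[:top_n])
    panel = pd.Index(pd.unique(pd.Series(panel))).intersection(shared)
    if len(panel) < 3:
        raise ValueError(f"DEG panel too small ({len(panel)} genes)")
    ma = _cluster_means(norm_a, labels_a, panel)
    mb = _cluster_means(norm_b, labels_b, panel)
    out = pd.DataFrame(index=ma.columns, columns=mb.columns, dtype=float)
    for ca in ma.columns:
        for cb in mb.columns:
            out.loc[ca, cb] = stats.spearmanr(ma[ca], mb[cb]).statistic
    return out
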