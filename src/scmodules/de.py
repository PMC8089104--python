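"""Hurdle-model differential expression for zero-inflated log-normalized data.

Each gene is tested one cluster against the rest with a two-part hurdle
likelihood-ratio test in the MAST style: a Bernoulli component compares
detection rates (expression > 0) between the groups, a Gaussian component
compares the positive log-expression values, and the two LR statistics are
summed with their degrees of freedom for a single chi-square p-value.  The
fold change is the difference of group means of log-normalized expression
(zeros included) divided by ln 2, i.e. a log2 fold change on the normalized
scale.

Two threshold regimes are supported downstream: strict marker calling
(log2FC > 0.25, FDR < 0.01, up-regulated only) and a permissive selection
(|log2FC| > 0.1, raw p < 0.1) whose union across clusters feeds gene-module
discovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import CountMatrix

__all__ = [
    "hurdle_de",
    "de_all_clusters",
    "bh_fdr",
    "marker_genes",
    "permissive_gene_set",
]

DE_COLUMNS = ["gene", "cluster", "log2FC", "p_value", "fdr", "pct_in", "pct_out"]


def _bernoulli_lr(k1: int, n1: int, k0: int, n0: int) -> tuple[float, int]:
    """LR statistic and df for equal detection probability across two groups."""
    k, n = k1 + k0, n1 + n0
    if k == 0 or k == n:
        return 0.0, 0  # no detection variation: component uninformative
    def ll(k, n):
        if k == 0 or k == n:
            return 0.0
        p = k / n
        return k * np.log(p) + (n - k) * np.log1p(-p)
    lr = 2.0 * (ll(k1, n1) + ll(k0, n0) - ll(k, n))
    return max(lr, 0.0), 1


def _gaussian_lr(y1: np.ndarray, y0: np.ndarray) -> tuple[float, int]:
    """LR statistic and df for equal means of positive expression values."""
    n1, n0 = len(y1), len(y0)
    if n1 == 0 or n0 == 0 or n1 + n0 < 3:
        return 0.0, 0
    y = np.concatenate([y1, y0])
    rss0 = np.sum((y - y.mean()) ** 2)
    rss1 = np.sum((y1 - y1.mean()) ** 2) + np.sum((y0 - y0.mean()) ** 2)
    if rss0 <= 0:
        return 0.0, 0
    if rss1 <= 0:
        return np.inf, 1
    return len(y) * np.log(rss0 / rss1), 1


def hurdle_de(norm: CountMatrix, labels: pd.Series, cluster) -> pd.DataFrame:
    """One-vs-rest hurdle test of every gene for one cluster.

    ``labels`` maps each cell id to its cluster.  Returns a DataFrame with
    columns gene, cluster, log2FC, p_value, fdr (BH within this cluster's
    family), pct_in, pct_out.  Genes with no expression in either group are
    untestable: p = 1, log2FC = 0.
    """
    labels = labels.loc[norm.cells]
    in_mask = (labels == cluster).to_numpy()
    if in_mask.sum() == 0 or (~in_mask).sum() == 0:
        raise ValueError(f"cluster {cluster!r}: both groups must be non-empty")
    x_in = norm.values[:, in_mask]
    x_out = norm.values[:, ~in_mask]
    n1, n0 = x_in.shape[1], x_out.shape[1]

    log2fc = (x_in.mean(axis=1) - x_out.mean(axis=1)) / np.log(2.0)
    det_in = (x_in > 0).sum(axis=1)
    det_out = (x_out > 0).sum(axis=1)

    pvals = np.ones(norm.shape[0])
    for g in range(norm.shape[0]):
        lr_b, df_b = _bernoulli_lr(int(det_in[g]), n1, int(det_out[g]), n0)
        y1 = x_in[g][x_in[g] > 0]
        y0 = x_out[g][x_out[g] > 0]
        lr_c, df_c = _gaussian_lr(y1, y0)
        df = df_b + df_c
        if df > 0:
            pvals[g] = stats.chi2.sf(lr_b + lr_c, df)
    untestable = (det_in + det_out) == 0
    pvals[untestable] = 1.0
    log2fc[untestable] = 0.0

    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "cluster": cluster,
            "log2FC": log2fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "pct_in": det_in / n1,
            "pct_out": det_out / n0,
        }
    ).reset_index(drop=True)


def de_all_clusters(norm: CountMatrix, labels: pd.Series) -> pd.DataFrame:
    """Concatenated one-vs-rest hurdle DE over every cluster label."""
    tables = [hurdle_de(norm, labels, c) for c in sorted(pd.unique(labels))]
    return pd.concat(tables, ignore_index=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def marker_genes(de: pd.DataFrame, lfc_min: float = 0.25, fdr_max: float = 0.01) -> dict:
    """Per-cluster up-regulated marker lists: log2FC > lfc_min AND fdr < fdr_max."""
    keep = de[(de["log2FC"] > lfc_min) & (de["fdr"] < fdr_max)]
    return {
        c: sub["gene"].tolist()
        for c, sub in keep.groupby("cluster", sort=True)
    }


def permissive_gene_set(
    de_all: pd.DataFrame, lfc_abs_min: float = 0.1, p_max: float = 0.1
) -> list:
    """Union over clusters of genes with |log2FC| > lfc_abs_min and raw p < p_max.

    This permissive two-sided selection feeds co-expression module discovery;
    the order of the returned list is deterministic (first passing occurrence).
    """
    keep = de_all[(de_all["log2FC"].abs() > lfc_abs_min) & (de_all["p_value"] < p_max)]
    seen, out = set(), []
    for g in keep["gene"]:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out
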