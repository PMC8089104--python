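"""Gene co-expression module discovery on a power-free topological overlap matrix.

The construction follows WGCNA with one deliberate deviation: the unsigned
adjacency a_ij = |r_ij| (pairwise Pearson correlation of genes across cells)
is used directly, with no soft-threshold power.  In sparse single-cell data
even strong correlations rarely approach 1, so raising the adjacency to a
power would flatten the whole matrix toward 0; skipping it preserves the
dynamic range.  The unsigned topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu

is then cut into a fixed number of modules (100 by default) by agglomerative
hierarchical clustering with Ward's squared linkage (ward.D2) on the
dissimilarity 1 - TOM.  Per-cell module scores are the mean of the module
genes' min-max-normalized expression, so every score lies in [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .qc import CountMatrix

__all__ = [
    "correlation_adjacency",
    "topological_overlap",
    "cut_modules",
    "module_scores",
    "module_knn_graph",
]


def correlation_adjacency(expr: CountMatrix, signed: bool = False) -> np.ndarray:
    """Gene-gene adjacency from Pearson correlation, no soft-threshold power.

    Unsigned by default (a = |r|); ``signed=True`` gives a = (1 + r) / 2.
    Constant genes have undefined correlations and are rejected by name.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 cells for correlation adjacency")
    sd = expr.values.std(axis=1)
    if np.any(sd == 0):
        bad = list(expr.gene_ids[sd == 0])
        raise ValueError(f"constant genes have no correlation structure: {bad}")
    r = np.corrcoef(expr.values)
    adj = (1.0 + r) / 2.0 if signed else np.abs(r)
    adj = np.clip(adj, 0.0, 1.0)
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM of an adjacency matrix (matrix-product implementation)."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any((adj < 0) | (adj > 1)):
        raise ValueError("adjacency entries outside [0, 1]")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)  # internal: sums exclude the diagonal
    k = a.sum(axis=1)
    # l_ij = sum_u a_iu a_uj excluding u in {i, j}; diagonal of `a` is 0 already
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def cut_modules(tom: np.ndarray, gene_ids, n_modules: int = 100) -> pd.Series:
    """Cut a ward.D2 dendrogram of 1 - TOM into exactly ``n_modules`` modules.

    Module ids run 1..n_modules, assigned by decreasing module size with ties
    broken by smallest gene position, so labels are reproducible.
    """
    gene_ids = pd.Index(gene_ids)
    n = tom.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match TOM size")
    if n_modules > n:
        raise ValueError(f"n_modules={n_modules} exceeds gene count {n}")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    z = linkage(squareform(dissim, checks=False), method="ward")
    raw = fcluster(z, t=n_modules, criterion="maxclust")
    # relabel: largest module first, ties by earliest member
    order = sorted(
        pd.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=gene_ids, name="module")


def module_scores(expr: CountMatrix, assignment: pd.Series) -> pd.DataFrame:
    """Per-cell module scores in [0, 1]: mean of min-max-normalized gene values.

    Each gene is min-max normalized across cells; a module's score in a cell
    is the mean over its genes.  Constant genes carry no pattern and
    contribute 0.  Result is modules x cells.
    """
    if not assignment.index.isin(expr.gene_ids).all():
        raise ValueError("assignment contains genes absent from the matrix")
    sub = expr.subset(gene_ids=assignment.index)
    v = sub.values
    lo = v.min(axis=1, keepdims=True)
    rng = v.max(axis=1, keepdims=True) - lo
    const = rng[:, 0] == 0
    rng[const] = 1.0
    normed = (v - lo) / rng
    normed[const] = 0.0
    scores = {}
    for mod, genes in assignment.groupby(assignment).groups.items():
        gi = sub.gene_ids.get_indexer(genes)
        if len(gi) == 0:
            raise ValueError(f"empty module {mod}")
        scores[mod] = normed[gi].mean(axis=0)
    out = pd.DataFrame(scores, index=sub.cells).T.sort_index()
    out.index.name = "module"
    return out


def module_knn_graph(scores: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Module similarity graph: each module linked to its k most-correlated peers.

    Pearson correlation between module score vectors; directed top-k lists are
    symmetrized into an undirected edge list (module_a, module_b, weight)
    with the correlation as weight.  Constant score vectors cannot rank and
    are excluded with a warning.
    """
    mods = scores.index
    if k >= len(mods):
        raise ValueError(f"k={k} must be below the number of modules {len(mods)}")
    sd = scores.to_numpy().std(axis=1)
    if np.any(sd == 0):
        warnings.warn(f"constant module score vectors excluded: {list(mods[sd == 0])}")
    active = mods[sd > 0]
    r = np.corrcoef(scores.loc[active].to_numpy())
    edges = set()
    for ia, a in enumerate(active):
        order = np.argsort(-r[ia], kind="stable")
        picked = [ib for ib in order if ib != ia][:k]
        for ib in picked:
            edges.add(tuple(sorted((a, active[ib]))) + (r[ia, ib],))
    # symmetrized union; dedupe keeps a single weight per undirected pair
    uniq = {}
    for a, b, w in edges:
        uniq[(a, b)] = w
    out = pd.DataFrame(
        [(a, b, w) for (a, b), w in sorted(uniq.items())],
        columns=["module_a", "module_b", "weight"],
    )
    return out
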