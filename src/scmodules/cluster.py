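"""HVG selection, PCA, KNN/SNN graph construction and Louvain clustering.

The workflow mirrors the common Seurat-style recipe for full-length
single-cell data: highly variable genes are picked by excess variance over a
fitted mean-variance trend, cells are embedded with PCA (50 components by
default), a k=10 nearest-neighbor graph is built on the embedding, spurious
edges are pruned by shared-nearest-neighbor Jaccard similarity (threshold
1/15), and communities are found with Louvain modularity optimization
(resolution 2.4 by default).  KNN search is exact rather than approximate:
at the scales this package targets, exactness costs nothing and removes a
source of irreproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .qc import CountMatrix

__all__ = [
    "Embedding",
    "select_hvgs",
    "run_pca",
    "build_knn_graph",
    "prune_snn",
    "louvain_cluster",
]


@dataclass
class Embedding:
    """Cells x components PCA embedding with per-component variance shares."""

    coords: np.ndarray
    variance_share: np.ndarray
    cells: pd.Index

    def __post_init__(self):
        if np.any(np.diff(self.variance_share) > 1e-12):
            raise ValueError("variance shares must be non-increasing")


def select_hvgs(norm: CountMatrix, n_hvg: int, trend: str = "lowess") -> pd.Index:
    """Select highly variable genes by excess variance over a mean-variance trend.

    A trend of per-gene variance against per-gene mean is fit across all
    genes (lowess by default, ``trend="poly"`` for a quadratic fit); genes
    are ranked by observed variance minus the trend value at their mean and
    the top ``n_hvg`` returned.  Ties fall back to gene order, so the
    degenerate all-equal case is deterministic.
    """
    n_genes = norm.shape[0]
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {n_genes}")
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1, ddof=1)
    if np.allclose(var, var[0]) and np.allclose(mean, mean[0]):
        resid = np.zeros(n_genes)
    elif trend == "lowess":
        fit = lowess(var, mean, frac=0.3, return_sorted=False)
        resid = var - fit
    elif trend == "poly":
        coef = np.polyfit(mean, var, deg=2)
        resid = var - np.polyval(coef, mean)
    else:
        raise ValueError(f"unknown trend method {trend!r}")
    # stable argsort on negated residuals: ties keep gene order
    order = np.argsort(-resid, kind="stable")
    return norm.gene_ids[order[:n_hvg]]


def run_pca(scaled: CountMatrix, n_components: int = 50) -> Embedding:
    """PCA on cells over the (HVG-restricted) scaled matrix.

    Components are sign-fixed so the largest-magnitude gene loading is
    positive.  If the matrix rank cannot support the requested number of
    components the embedding is truncated with a warning.
    """
    x = scaled.values.T  # cells x genes
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in scaled matrix")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=min(n_components, max_rank), svd_solver="full")
    coords = pca.fit_transform(x)
    # drop numerically null components (input rank below the request)
    ev = pca.explained_variance_
    rank = int(np.sum(ev > max(ev[0], 1e-30) * 1e-12)) if ev.size else 0
    if rank < n_components:
        warnings.warn(
            f"matrix supports only {rank} components, not {n_components}; truncating"
        )
    coords = coords[:, :rank]
    # sign convention: largest-|loading| positive per component
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return Embedding(coords, pca.explained_variance_ratio_[:rank].copy(), scaled.cells)


def build_knn_graph(emb: Embedding, k: int = 10):
    """Exact Euclidean KNN graph, symmetrized union of directed neighbor lists.

    Returns ``(graph, knn_lists)`` where ``graph`` is an undirected
    ``networkx.Graph`` over cell indices with unit edge weights and
    ``knn_lists`` maps each cell index to its set of k nearest neighbors
    (self excluded; distance ties broken by index order).
    """
    n = emb.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below the number of cells {n}")
    # dense exact search; stable sort gives index-order tie-breaks
    from scipy.spatial.distance import cdist

    dist = cdist(emb.coords, emb.coords)
    np.fill_diagonal(dist, np.inf)
    knn_lists = {}
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        knn_lists[i] = set(order[:k].tolist())
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, neigh in knn_lists.items():
        for j in neigh:
            g.add_edge(i, j, weight=1.0)
    return g, knn_lists


def prune_snn(graph: nx.Graph, knn_lists: dict, jaccard_min: float = 1 / 15) -> nx.Graph:
    """Shared-nearest-neighbor pruning of a KNN graph.

    An edge (i, j) survives iff the Jaccard similarity of the endpoints'
    neighbor lists is at least ``jaccard_min``; surviving edges are
    reweighted by that similarity.  Never adds edges.
    """
    pruned = nx.Graph()
    pruned.add_nodes_from(graph.nodes)
    for i, j in graph.edges:
        inter = len(knn_lists[i] & knn_lists[j])
        union = len(knn_lists[i] | knn_lists[j])
        jac = inter / union if union else 0.0
        if jac >= jaccard_min:
            pruned.add_edge(i, j, weight=jac)
    return pruned


def louvain_cluster(graph: nx.Graph, resolution: float = 2.4, seed: int = 0) -> pd.Series:
    """Louvain community detection at the given modularity resolution.

    Returns a per-node series of contiguous 0-based cluster ids, deterministic
    for a fixed seed.  Isolated nodes become singleton clusters.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    # stable ids: order communities by their smallest node
    comms = sorted(comms, key=min)
    labels = pd.Series(index=sorted(graph.nodes), dtype=int, name="cluster")
    for cid, comm in enumerate(comms):
        for node in comm:
            labels[node] = cid
    return labels
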