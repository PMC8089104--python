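import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scmodules import (
    CountMatrix,
    build_knn_graph,
    louvain_cluster,
    prune_snn,
    run_pca,
    select_hvgs,
)
from scmodules.cluster import Embedding
from scmodules.synthetic import synthetic_annotation


def _matrix(values, signed=False):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        values,
        synthetic_annotation(values.shape[0]),
        pd.Index([f"c{i}" for i in range(values.shape[1])]),
        signed=signed,
    )


def _embed(coords):
    coords = np.asarray(coords, dtype=float)
    share = np.full(coords.shape[1], 1.0 / coords.shape[1])
    return Embedding(coords, share, pd.Index([f"c{i}" for i in range(len(coords))]))


class TestSelectHVGs:
    def test_planted_high_dispersion_genes_recovered(self):
        rng = np.random.default_rng(0)
        n_genes, n_cells = 1000, 300
        base = rng.normal(2.0, 0.1, (n_genes, n_cells))
        planted = rng.choice(n_genes, 50, replace=False)
        base[planted] += rng.normal(0, 2.0, (50, n_cells))
        m = _matrix(np.abs(base))
        top = select_hvgs(m, 50)
        hits = len(set(top) & set(m.gene_ids[planted]))
        assert hits >= 45

    def test_degenerate_ties_fall_back_to_gene_order(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        m = _matrix(values)
        assert list(select_hvgs(m, 3)) == list(m.gene_ids[:3])

    def test_outlier_gene_ranked_first(self):
        # one gene with ~9x the trend variance at a typical mean leads the ranking
        rng = np.random.default_rng(1)
        values = rng.normal(5, 1, (50, 200))
        values[17] = 5 + 3 * rng.normal(0, 1, 200)
        top = select_hvgs(_matrix(np.abs(values)), 5)
        assert top[0] == "g00017"

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            select_hvgs(_matrix(np.ones((5, 4))), 6)


class TestRunPCA:
    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(0, 1, (10, 50)), signed=True)
        emb = run_pca(m, n_components=10)
        x = m.values.T
        centered = x - x.mean(axis=0)
        # full-rank embedding preserves the centered data's geometry exactly
        from sklearn.decomposition import PCA

        p = PCA(n_components=10, svd_solver="full").fit(x)
        recon = p.inverse_transform(p.transform(x)) - x.mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-8)
        assert emb.coords.shape == (50, 10)
        assert np.all(np.diff(emb.variance_share) <= 1e-12)
        assert emb.variance_share.sum() <= 1 + 1e-9

    def test_rank_deficient_truncates_with_warning(self):
        rng = np.random.default_rng(3)
        low = rng.normal(0, 1, (2, 40))
        values = np.vstack([low, low, low])  # rank 2
        with pytest.warns(UserWarning, match="truncating"):
            emb = run_pca(_matrix(values, signed=True), n_components=5)
        assert emb.coords.shape[1] <= 5

    def test_isotropic_input_has_flat_spectrum(self):
        # sample eigenvalue spread shrinks toward 1 as cells/genes grows
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(0, 1, (50, 20000)), signed=True)
        emb = run_pca(m, n_components=49)
        share = emb.variance_share
        assert share.max() / share.min() < 1.5


class TestKNNGraph:
    def test_collinear_points(self):
        g, lists = build_knn_graph(_embed([[0.0], [1.0], [2.0]]), k=1)
        assert lists[0] == {1} and lists[2] == {1}
        assert g.has_edge(0, 1) and g.has_edge(1, 2)

    def test_no_cross_blob_edges(self):
        rng = np.random.default_rng(5)
        blob1 = rng.normal(0, 0.1, (20, 3))
        blob2 = rng.normal(100, 0.1, (20, 3))
        g, _ = build_knn_graph(_embed(np.vstack([blob1, blob2])), k=5)
        cross = [(a, b) for a, b in g.edges if (a < 20) != (b < 20)]
        assert cross == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 1, (200, 5))
        g, lists = build_knn_graph(_embed(coords), k=4)
        # brute force: full distance matrix, take 4 smallest per row
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        expected_edges = set()
        for i in range(200):
            for j in np.argsort(d[i])[:4]:
                expected_edges.add(tuple(sorted((i, int(j)))))
        assert set(tuple(sorted(e)) for e in g.edges) == expected_edges

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            build_knn_graph(_embed([[0.0], [1.0]]), k=2)


class TestPruneSNN:
    def test_identical_lists_kept_with_weight_one(self):
        g = nx.Graph([(0, 1)])
        lists = {0: {2, 3, 4}, 1: {2, 3, 4}}
        pruned = prune_snn(g, lists, 1 / 15)
        assert pruned[0][1]["weight"] == 1.0

    def test_disjoint_lists_pruned(self):
        g = nx.Graph([(0, 1)])
        pruned = prune_snn(g, {0: {2, 3}, 1: {4, 5}}, 1 / 15)
        assert pruned.number_of_edges() == 0
        assert pruned.number_of_nodes() == 2  # nodes preserved

    def test_boundary_jaccard_kept(self):
        # |inter|=2, |union|=18 -> 1/9 >= 1/15
        g = nx.Graph([(0, 1)])
        lists = {0: set(range(2, 12)), 1: {2, 3} | set(range(20, 28))}
        pruned = prune_snn(g, lists, 1 / 15)
        assert pruned.has_edge(0, 1)
        assert pruned[0][1]["weight"] == pytest.approx(2 / 18)

    def test_never_adds_edges(self):
        rng = np.random.default_rng(7)
        g, lists = build_knn_graph(_embed(rng.normal(0, 1, (50, 3))), k=5)
        pruned = prune_snn(g, lists)
        assert set(pruned.edges) <= set(g.edges)


class TestLouvain:
    def _two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(20), nx.complete_graph(20))
        nx.set_edge_attributes(g, 1.0, "weight")
        return g

    def test_two_disconnected_cliques(self):
        labels = louvain_cluster(self._two_cliques(), resolution=1.0, seed=0)
        assert labels.nunique() == 2
        assert labels[:20].nunique() == 1 and labels[20:].nunique() == 1

    def test_deterministic_for_fixed_seed(self):
        g = self._two_cliques()
        a = louvain_cluster(g, resolution=1.0, seed=3)
        b = louvain_cluster(g, resolution=1.0, seed=3)
        assert (a == b).all()

    def test_planted_sbm_recovered(self):
        rng = np.random.default_rng(8)
        sizes = [50, 50, 50, 50]
        p = np.full((4, 4), 0.01)
        np.fill_diagonal(p, 0.5)
        g = nx.stochastic_block_model(sizes, p, seed=8)
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = louvain_cluster(g, resolution=1.0, seed=0)
        truth = np.repeat(np.arange(4), 50)
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.95

    def test_order_invariance_up_to_relabeling(self):
        g = self._two_cliques()
        perm = np.random.default_rng(9).permutation(40)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(40)})
        la = louvain_cluster(g, resolution=1.0, seed=0)
        lb = louvain_cluster(h, resolution=1.0, seed=0)
        remapped = [lb[perm[i]] for i in range(40)]
        assert adjusted_rand_score(la.to_numpy(), remapped) == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph(), seed=0)
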