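import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from scmodules import (
    CountMatrix,
    correlation_adjacency,
    cut_modules,
    lognormalize,
    module_knn_graph,
    module_scores,
    topological_overlap,
)
from scmodules.synthetic import synthetic_annotation


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        values,
        synthetic_annotation(values.shape[0]),
        pd.Index([f"c{i}" for i in range(values.shape[1])]),
    )


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def tom_brute_force(adj):
    """Triple-loop reference implementation of the unsigned TOM."""
    n = adj.shape[0]
    tom = np.ones((n, n))
    k = np.array([adj[i].sum() - adj[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def ward_d2_oracle(dissim):
    """Brute-force ward.D2 merge heights via the Lance-Williams recursion."""
    n = dissim.shape[0]
    d2 = dissim.astype(float) ** 2  # recursion runs on squared dissimilarities
    active = {i: ([i], 1) for i in range(n)}
    d = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(
            ((tuple(sorted(k)), v) for k, v in d.items() if all(x in active for x in k)),
            key=lambda kv: (kv[1], kv[0]),
        )
        heights.append(np.sqrt(dij))
        ni, nj = active[i][1], active[j][1]
        for m in list(active):
            if m in (i, j):
                continue
            nm = active[m][1]
            dim, djm = d[frozenset((i, m))], d[frozenset((j, m))]
            d[frozenset((next_id, m))] = (
                (ni + nm) * dim + (nj + nm) * djm - nm * dij
            ) / (ni + nj + nm)
        active[next_id] = (active[i][0] + active[j][0], ni + nj)
        del active[i], active[j]
        next_id += 1
    return np.array(heights)


class TestAdjacency:
    def test_identical_and_negated_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, 50)
        shift = base.max() + base.min()
        m = _matrix(np.vstack([base, base, shift - base, rng.normal(5, 1, 50) ** 2]))
        adj = correlation_adjacency(m)
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 2] == pytest.approx(1.0)  # unsigned: anticorrelation -> 1

    def test_signed_option(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 1, 60)
        m = _matrix(np.vstack([base, 10 - base + base.max()]))
        adj = correlation_adjacency(m, signed=True)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_independent_genes_near_zero(self):
        rng = np.random.default_rng(2)
        m = _matrix(np.abs(rng.normal(5, 1, (2, 10000))))
        adj = correlation_adjacency(m)
        assert adj[0, 1] < 0.05

    def test_constant_gene_named_in_error(self):
        values = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="g00000"):
            correlation_adjacency(_matrix(values))


class TestTOM:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            adj = random_adjacency(rng, 30)
            np.testing.assert_allclose(
                topological_overlap(adj), tom_brute_force(adj), atol=1e-10
            )

    def test_zero_offdiagonal(self):
        tom = topological_overlap(np.eye(4))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_clique_closed_form(self):
        adj = np.ones((4, 4))
        tom = topological_overlap(adj)
        np.testing.assert_allclose(tom, 1.0)  # (2+1)/(3+1-1) = 1

    def test_hand_evaluated_triangle(self):
        adj = np.array([[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1]])
        tom = topological_overlap(adj)
        assert tom[0, 1] == pytest.approx(0.5)  # (0 + 0.5)/(0.5 + 1 - 0.5)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(4)
        adj = random_adjacency(rng, 40)
        tom = topological_overlap(adj)
        assert np.all((tom >= -1e-12) & (tom <= 1 + 1e-12))
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_monotone_in_shared_neighbors(self):
        rng = np.random.default_rng(5)
        adj = random_adjacency(rng, 10)
        before = topological_overlap(adj)[0, 1]
        bumped = adj.copy()
        bumped[4, 5] = bumped[5, 4] = min(1.0, adj[4, 5] + 0.3)
        # raising a_uv for u,v outside {0,1} cannot decrease l_01 (k unchanged
        # for 0 and 1), so TOM_01 never drops
        after = topological_overlap(bumped)[0, 1]
        assert after >= before - 1e-12


class TestCutModules:
    def test_each_gene_its_own_module(self):
        rng = np.random.default_rng(6)
        adj = random_adjacency(rng, 8)
        tom = topological_overlap(adj)
        ass = cut_modules(tom, [f"g{i}" for i in range(8)], n_modules=8)
        assert ass.nunique() == 8

    def test_perfect_blocks_recovered(self):
        tom = np.zeros((20, 20))
        tom[:10, :10] = 1.0
        tom[10:, 10:] = 1.0
        ass = cut_modules(tom, [f"g{i}" for i in range(20)], n_modules=2)
        assert ass.iloc[:10].nunique() == 1
        assert ass.iloc[10:].nunique() == 1
        assert ass.iloc[0] != ass.iloc[10]

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(7)
        for n in (10, 15, 20):
            adj = random_adjacency(rng, n)
            dissim = 1 - topological_overlap(adj)
            np.fill_diagonal(dissim, 0.0)
            z = linkage(squareform(dissim, checks=False), method="ward")
            np.testing.assert_allclose(z[:, 2], ward_d2_oracle(dissim), atol=1e-8)

    def test_module_ids_ordered_by_size(self):
        tom = np.zeros((15, 15))
        tom[:10, :10] = 1.0
        tom[10:, 10:] = 1.0
        ass = cut_modules(tom, [f"g{i}" for i in range(15)], n_modules=2)
        assert (ass.iloc[:10] == 1).all() and (ass.iloc[10:] == 2).all()

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            cut_modules(np.eye(3), ["a", "b", "c"], n_modules=4)


class TestModuleScores:
    def test_single_gene_minmax(self):
        m = _matrix([[0.0, 5.0, 10.0]])
        ass = pd.Series([1], index=m.gene_ids)
        scores = module_scores(m, ass)
        np.testing.assert_allclose(scores.loc[1], [0.0, 0.5, 1.0])

    def test_constant_genes_contribute_zero(self):
        m = _matrix([[3.0, 3.0, 3.0]])
        scores = module_scores(m, pd.Series([1], index=m.gene_ids))
        np.testing.assert_allclose(scores.loc[1], 0.0)

    def test_two_gene_average(self):
        m = _matrix([[0.0, 10.0], [10.0, 0.0]])
        scores = module_scores(m, pd.Series([1, 1], index=m.gene_ids))
        np.testing.assert_allclose(scores.loc[1], [0.5, 0.5])

    def test_all_scores_in_unit_interval(self, norm_planted):
        genes = norm_planted.gene_ids[:100]
        ass = pd.Series(np.arange(100) % 10 + 1, index=genes)
        scores = module_scores(norm_planted, ass)
        assert scores.to_numpy().min() >= 0 and scores.to_numpy().max() <= 1


class TestModuleKNNGraph:
    def test_correlation_ranking(self):
        rng = np.random.default_rng(8)
        s1 = rng.normal(0, 1, 200)
        s2 = s1 + 0.2 * rng.normal(0, 1, 200)
        s3 = rng.normal(0, 1, 200)
        scores = pd.DataFrame([s1, s2, s3], index=[1, 2, 3])
        edges = module_knn_graph(scores, k=1)
        pairs = set(map(tuple, edges[["module_a", "module_b"]].to_numpy()))
        assert (1, 2) in pairs

    def test_complete_graph_at_max_k(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.random((4, 50)), index=[1, 2, 3, 4])
        edges = module_knn_graph(scores, k=3)
        assert len(edges) == 6

    def test_constant_vector_warned_and_excluded(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(
            np.vstack([np.ones(30), rng.random((3, 30))]), index=[1, 2, 3, 4]
        )
        with pytest.warns(UserWarning, match="constant"):
            edges = module_knn_graph(scores, k=1)
        assert 1 not in set(edges["module_a"]) | set(edges["module_b"])


class TestEndToEndRecovery:
    def test_planted_modules_recovered(self, planted_dataset, norm_planted):
        _, _, truth = planted_dataset
        planted = truth.module_assignment.dropna()
        sub = norm_planted.subset(gene_ids=planted.index)
        adj = correlation_adjacency(sub)
        ass = cut_modules(topological_overlap(adj), sub.gene_ids, n_modules=10)
        assert adjusted_rand_score(planted.to_numpy(), ass.to_numpy()) >= 0.8

    def test_spearman_adjacency_gives_similar_recovery(self, planted_dataset, norm_planted):
        """Swapping Pearson for Spearman moves recovery ARI by < 0.1."""
        from scipy.stats import rankdata

        _, _, truth = planted_dataset
        planted = truth.module_assignment.dropna()
        sub = norm_planted.subset(gene_ids=planted.index)
        ari = {}
        for method in ("pearson", "spearman"):
            values = sub.values if method == "pearson" else rankdata(sub.values, axis=1)
            adj = np.clip(np.abs(np.corrcoef(values)), 0, 1)
            np.fill_diagonal(adj, 1.0)
            ass = cut_modules(topological_overlap(adj), sub.gene_ids, n_modules=10)
            ari[method] = adjusted_rand_score(planted.to_numpy(), ass.to_numpy())
        assert abs(ari["pearson"] - ari["spearman"]) < 0.1
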