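"""PCA, kNN/SNN graph construction and modularity clustering."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from myomac import clustering as cl
from myomac.containers import ExpressionMatrix


def _expr(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells)


class TestPca:
    def test_collinear_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)
        vals = np.vstack([2 * t + 1, 3 * t + 0.5])  # 2 genes on a line
        res = cl.pca_embed(_expr(vals), n_pcs=2, unit_scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_leaves_spectrum_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 40))  # genes x cells
        res1 = cl.pca_embed(X, n_pcs=5, unit_scale=False)
        # orthogonal rotation in gene space
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        res2 = cl.pca_embed(Q @ X, n_pcs=5, unit_scale=False)
        np.testing.assert_allclose(res1.explained_variance_ratio,
                                   res2.explained_variance_ratio, atol=1e-10)

    def test_full_reconstruction_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 25))
        res = cl.pca_embed(X, n_pcs=6)
        standardized = ((X.T - res.mean) / res.scale)
        recon = res.coords @ res.components
        np.testing.assert_allclose(recon, standardized, atol=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cl.pca_embed(np.ones((4, 10)), n_pcs=2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 30))
        res = cl.pca_embed(X, n_pcs=3)
        for j in range(3):
            lead = np.argmax(np.abs(res.components[j]))
            assert res.components[j, lead] > 0


class TestKnn:
    def test_collinear_hand_case(self):
        emb = np.array([[0.0], [1.0], [3.0]])
        knn = cl.knn_graph(emb, k=1)
        assert knn.ravel().tolist() == [1, 0, 1]

    def test_k_equals_n_minus_one_is_complete(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(7, 3))
        knn = cl.knn_graph(emb, k=6)
        for i in range(7):
            assert sorted(knn[i]) == sorted(set(range(7)) - {i})

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(200, 5))
        knn = cl.knn_graph(emb, k=10)
        # independent oracle: explicit loops over pairwise distances
        for i in rng.choice(200, 25, replace=False):
            d = [(np.sum((emb[i] - emb[j]) ** 2), j) for j in range(200) if j != i]
            d.sort()
            expected = [j for _, j in d[:10]]
            assert knn[i].tolist() == expected

    def test_duplicate_points_tie_broken_by_index(self):
        emb = np.zeros((4, 2))
        knn = cl.knn_graph(emb, k=2)
        assert knn[0].tolist() == [1, 2]
        assert knn[3].tolist() == [0, 1]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cl.knn_graph(np.zeros((3, 2)), k=3)


class TestSnn:
    def test_identical_neighbor_sets_weight_one(self):
        # all 4 cells share the neighbor set {0,1,2,3} (self included)
        knn = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        snn = cl.snn_from_knn(knn, prune=0.0)
        w = snn.weights.toarray()
        off = w[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(w), 0.0)

    def test_disjoint_sets_no_edge(self):
        knn = np.array([[1], [0], [3], [2]])
        snn = cl.snn_from_knn(knn, prune=0.0)
        w = snn.weights.toarray()
        assert w[0, 2] == 0 and w[0, 3] == 0 and w[1, 2] == 0

    def test_hand_jaccard(self):
        # sets {0,2,3} and {1,2,3}: intersection 2, union 4 -> 0.5
        knn = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])
        snn = cl.snn_from_knn(knn, prune=0.0)
        assert snn.weights[0, 1] == pytest.approx(0.5)

    def test_prune_drops_weak_edges(self):
        # every pairwise Jaccard overlap here is exactly 0.5
        knn = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])
        assert cl.snn_from_knn(knn, prune=0.6).weights.nnz == 0  # 0.5 < 0.6
        assert cl.snn_from_knn(knn, prune=0.5).weights.nnz > 0   # boundary kept

    def test_weights_symmetric_bounded(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(60, 4))
        snn = cl.snn_from_knn(cl.knn_graph(emb, k=8))
        w = snn.weights
        assert (abs(w - w.T)).nnz == 0
        assert w.data.max() <= 1.0 and w.data.min() > 0


def _two_cliques(n1: int, n2: int) -> sp.csr_matrix:
    n = n1 + n2
    A = np.zeros((n, n))
    A[:n1, :n1] = 1.0
    A[n1:, n1:] = 1.0
    np.fill_diagonal(A, 0.0)
    A[0, n1] = A[n1, 0] = 1.0  # single bridge
    return sp.csr_matrix(A)


class TestModularityCluster:
    def test_single_community_q_is_zero_at_unit_resolution(self):
        A = _two_cliques(5, 5)
        labels = np.zeros(10, dtype=int)
        assert cl.modularity(A, labels, resolution=1.0) == pytest.approx(0.0)

    def test_two_cliques_recovered(self):
        A = _two_cliques(20, 20)
        snn = cl.SnnGraph(A, prune=0.0, k=0)
        res = cl.modularity_cluster(snn, resolution=1.0, seed=0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:20])) == 1
        assert len(set(res.labels[20:])) == 1

    def test_two_cliques_partition_is_brute_force_optimum(self):
        # exhaustive search over all 2-subsets confirms the clique split
        # maximizes Q among bipartitions, and the algorithm finds it
        A = _two_cliques(5, 5)
        best_q, best_mask = -np.inf, None
        for bits in itertools.product([0, 1], repeat=9):
            labels = np.array((0,) + bits)
            q = cl.modularity(A, labels, resolution=1.0)
            if q > best_q:
                best_q, best_mask = q, labels
        assert best_mask.tolist() == [0] * 5 + [1] * 5
        res = cl.modularity_cluster(cl.SnnGraph(A, 0.0, 0), resolution=1.0, seed=0)
        assert res.modularity == pytest.approx(best_q, abs=1e-12)

    def test_no_edges_gives_singletons(self):
        empty = sp.csr_matrix((5, 5))
        res = cl.modularity_cluster(cl.SnnGraph(empty, 0.0, 0), seed=0)
        assert res.n_clusters == 5

    @pytest.mark.parametrize("seed", range(3))
    def test_incremental_q_matches_scratch(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        A = (rng.random((n, n)) < 0.12).astype(float) * rng.random((n, n))
        A = np.triu(A, 1)
        A = A + A.T
        snn = cl.SnnGraph(sp.csr_matrix(A), 0.0, 0)
        res = cl.modularity_cluster(snn, resolution=0.9, seed=seed)
        assert res.modularity_incremental == pytest.approx(res.modularity, abs=1e-10)

    def test_resolution_monotone_in_cluster_count(self):
        rng = np.random.default_rng(7)
        emb = np.vstack([rng.normal(loc=c, scale=0.4, size=(30, 3))
                         for c in (0.0, 3.0, 6.0)])
        snn = cl.snn_from_knn(cl.knn_graph(emb, k=10))
        counts = []
        for gamma in (0.2, 0.5, 0.8, 1.2, 2.0, 4.0):
            res = cl.modularity_cluster(snn, resolution=gamma, seed=1)
            counts.append(res.n_clusters)
        assert counts == sorted(counts)

    def test_relabelling_cells_permutes_assignments(self):
        A = _two_cliques(12, 12).toarray()
        rng = np.random.default_rng(9)
        perm = rng.permutation(24)
        Ap = A[np.ix_(perm, perm)]
        res = cl.modularity_cluster(cl.SnnGraph(sp.csr_matrix(A), 0.0, 0), seed=0)
        resp = cl.modularity_cluster(cl.SnnGraph(sp.csr_matrix(Ap), 0.0, 0), seed=0)
        # partitions agree up to label names
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(res.labels[perm], resp.labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        emb = rng.normal(size=(80, 4))
        snn = cl.snn_from_knn(cl.knn_graph(emb, k=10))
        a = cl.modularity_cluster(snn, seed=5)
        b = cl.modularity_cluster(snn, seed=5)
        assert (a.labels == b.labels).all()
        assert a.modularity == b.modularity
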