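"""Classical MDS, Isomap and LLE solvers."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import manifoldseg as ms
from manifoldseg.manifold import lle_embedding_cost


def procrustes_rmse(D_in, Y):
    """RMSE between input distances and embedded distances."""
    d_out = pdist(Y)
    d_in = squareform(D_in)
    return np.sqrt(np.mean((d_in - d_out) ** 2)) / max(d_in.max(), 1e-12)


class TestClassicalMds:
    def test_two_points_at_distance_five(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        emb = ms.classical_mds(D, 1)
        assert abs(emb.values[0, 0] - emb.values[1, 0]) == pytest.approx(5.0)

    def test_exact_recovery_of_planar_points(self, rng):
        X = rng.normal(size=(10, 2))
        D = squareform(pdist(X))
        emb = ms.classical_mds(D, 2)
        assert procrustes_rmse(D, emb.values) < 1e-8

    def test_eigenvalues_descending_and_nonneg_coords(self, rng):
        X = rng.normal(size=(20, 3))
        emb = ms.classical_mds(squareform(pdist(X)), 3)
        assert (np.diff(emb.eigenvalues) <= 1e-9).all()

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(15, 2))
        D = squareform(pdist(X))
        a = ms.classical_mds(D, 2).values
        b = ms.classical_mds(D, 2).values
        np.testing.assert_array_equal(a, b)
        for j in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0

    def test_infinite_entries_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="disconnected"):
            ms.classical_mds(D, 1)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ms.classical_mds(D, 1)

    def test_matches_sklearn_style_pca_embedding(self, rng):
        # classical MDS on Euclidean distances is equivalent to PCA
        # scores up to sign; cross-check distance preservation at d=2
        X = rng.normal(size=(30, 5))
        D = squareform(pdist(X))
        ours = ms.classical_mds(D, 2)
        from sklearn.decomposition import PCA
        scores = PCA(n_components=2).fit_transform(X)
        np.testing.assert_allclose(np.abs(ours.values), np.abs(scores),
                                   atol=1e-6)


class TestIsomap:
    def test_arc_embedding_monotone_in_arclength(self):
        t = np.linspace(0, np.pi, 40)
        X = np.column_stack([np.cos(t), np.sin(t), 0 * t])
        emb = ms.isomap(X, 2, 1)
        rho = spearmanr(emb.values[:, 0], t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_complete_graph_limit_equals_mds(self, rng):
        X = rng.normal(size=(25, 3))
        emb_iso = ms.isomap(X, 24, 2)
        emb_mds = ms.classical_mds(squareform(pdist(X)), 2)
        np.testing.assert_allclose(emb_iso.values, emb_mds.values, atol=1e-8)

    def test_matches_sklearn_isomap(self, rng):
        X = rng.normal(size=(60, 3)) * [3.0, 1.0, 0.3]
        ours = ms.isomap(X, 8, 2)
        sk = pytest.importorskip("sklearn.manifold").Isomap(
            n_neighbors=8, n_components=2).fit_transform(X)
        # same embedding up to per-column sign
        for j in range(2):
            col, ref = ours.values[:, j], sk[:, j]
            err = min(np.abs(col - ref).max(), np.abs(col + ref).max())
            assert err < 1e-6 * max(1.0, np.abs(ref).max())

    def test_disconnected_embeds_largest_component(self):
        X = np.vstack([np.random.default_rng(0).normal(size=(20, 2)),
                       np.random.default_rng(1).normal(size=(5, 2)) + 100.0])
        with pytest.warns(UserWarning, match="disconnected"):
            emb = ms.isomap(X, 3, 1)
        assert emb.included is not None
        assert emb.included.sum() == 20
        assert np.isnan(emb.values[~emb.included]).all()
        assert np.isfinite(emb.values[emb.included]).all()

    def test_channel_permutation_invariance(self, rng):
        X = rng.normal(size=(40, 4))
        emb1 = ms.isomap(X, 6, 2)
        emb2 = ms.isomap(X[:, [2, 0, 3, 1]], 6, 2)
        np.testing.assert_allclose(emb1.values, emb2.values, atol=1e-9)


class TestLle:
    def test_midpoint_gets_half_half_weights(self):
        X = np.array([[0.0], [1.0], [2.0]])
        g = ms.build_knn_graph(X, 2)
        W = ms.lle_weights(X, g, regularization=1e-9)
        row = W.values[1].toarray().ravel()
        assert row[0] == pytest.approx(0.5, abs=1e-6)
        assert row[2] == pytest.approx(0.5, abs=1e-6)

    def test_coincident_neighbour_takes_all_weight(self):
        # x0 == x1, x2 far away: reconstructing x0 uses x1 almost fully
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        g = ms.build_knn_graph(X, 2)
        W = ms.lle_weights(X, g, regularization=1e-12)
        row = W.values[0].toarray().ravel()
        assert row[1] == pytest.approx(1.0, abs=1e-3)

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(50, 4))
        g = ms.build_knn_graph(X, 7)
        W = ms.lle_weights(X, g)
        sums = np.asarray(W.values.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_sparsity_pattern_matches_graph(self, rng):
        X = rng.normal(size=(30, 3))
        g = ms.build_knn_graph(X, 4)
        W = ms.lle_weights(X, g)
        w_pat = (W.values != 0).toarray()
        g_pat = (g.adjacency != 0).toarray()
        assert not (w_pat & ~g_pat).any()

    def test_singular_gram_without_regularization_raises(self):
        # 5 neighbours in 1-D: local Gram is rank-1 and exactly singular
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        g = ms.build_knn_graph(X, 5)
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            ms.lle_weights(X, g, regularization=0.0)

    def test_line_ordering_preserved(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t, -t])
        emb = ms.lle(X, 2, 1)
        rho = spearmanr(emb.values[:, 0], t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_embedding_cost_optimal_under_rotation(self, rng):
        X = rng.normal(size=(40, 3))
        g = ms.build_knn_graph(X, 6)
        W = ms.lle_weights(X, g)
        emb = ms.lle_embed(W, 2)
        base = lle_embedding_cost(W, emb.values)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
            mixed = emb.values @ q + rng.normal(scale=0.1, size=emb.values.shape)
            mixed = (mixed - mixed.mean(0)) / mixed.std(0)  # comparable scale
            assert base <= lle_embedding_cost(W, mixed * np.sqrt(1.0)) + 1e-9

    def test_requested_dimension_too_large(self, rng):
        X = rng.normal(size=(6, 2))
        g = ms.build_knn_graph(X, 3)
        W = ms.lle_weights(X, g)
        with pytest.raises(ValueError, match="n >= d \\+ 2"):
            ms.lle_embed(W, 5)

    def test_channel_permutation_invariance(self, rng):
        X = rng.normal(size=(40, 4))
        a = ms.lle(X, 6, 1).values
        b = ms.lle(X[:, [3, 1, 0, 2]], 6, 1).values
        np.testing.assert_allclose(a, b, atol=1e-7)


class TestConnectComponents:
    def test_bridges_minimal_edges(self):
        X = np.vstack([np.zeros((5, 2)) + np.arange(5)[:, None] * 0.1,
                       np.zeros((5, 2)) + 50 + np.arange(5)[:, None] * 0.1])
        g = ms.build_knn_graph(X, 2)
        import scipy.sparse.csgraph as csg
        n0, _ = csg.connected_components(g.adjacency, directed=False)
        assert n0 == 2
        g2 = ms.connect_components(g, X)
        n1, _ = csg.connected_components(g2.adjacency, directed=False)
        assert n1 == 1
        # exactly one bridge (two symmetric entries) added
        assert g2.adjacency.nnz == g.adjacency.nnz + 2

    def test_connected_graph_returned_unchanged(self, rng):
        X = rng.normal(size=(20, 2))
        g = ms.build_knn_graph(X, 5)
        assert ms.connect_components(g, X) is g
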