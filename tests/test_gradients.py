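"""Connectopic-mapping core against brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

import wmgrad as w
from wmgrad.gradients import FISHER_CLIP, SimilarityGraph
from wmgrad.regions import BoldSeries, VoxelRegion


def series_from(data, tr=1.0):
    data = np.asarray(data, dtype=float)
    vox = np.array([[i, 0, 0] for i in range(data.shape[1])])
    region = VoxelRegion(shape=(data.shape[1], 1, 1), affine=np.eye(4),
                         voxels=vox)
    return BoldSeries(region=region, data=data, tr=tr)


def eta_squared_bruteforce(a, b):
    """Literal per-position loop over the defining sums of squares."""
    m = [(ai + bi) / 2 for ai, bi in zip(a, b)]
    grand = sum(m) / len(m)
    ss_w = sum((ai - mi) ** 2 + (bi - mi) ** 2 for ai, bi, mi in zip(a, b, m))
    ss_t = sum((ai - grand) ** 2 + (bi - grand) ** 2 for ai, bi in zip(a, b))
    return 1 - ss_w / ss_t


class TestGmPcaBasis:
    def test_rank_limited_data_zero_pads_tail(self, rng):
        latents = rng.normal(size=(20, 2))
        data = latents @ rng.normal(size=(2, 30))
        basis = w.gm_pca_basis(series_from(data))
        assert basis.shape == (20, 19)
        assert np.allclose(basis[:, 2:], 0)
        assert basis[:, :2].std(axis=0).min() > 0

    def test_total_variance_conserved(self, rng):
        data = rng.normal(size=(30, 50))
        basis = w.gm_pca_basis(series_from(data))
        centered = data - data.mean(axis=0)
        assert basis.var(axis=0, ddof=1).sum() == pytest.approx(
            centered.var(axis=0, ddof=1).sum(), rel=1e-6)

    def test_component_variances_match_svd_oracle(self, rng):
        data = rng.normal(size=(5, 4))
        basis = w.gm_pca_basis(series_from(data))
        s = np.linalg.svd(data - data.mean(axis=0), compute_uv=False)
        np.testing.assert_allclose(basis.var(axis=0, ddof=1),
                                   s ** 2 / (5 - 1), atol=1e-10)


class TestFingerprints:
    def test_self_correlation_clipped(self, rng):
        basis = rng.normal(size=(100, 5))
        wm = series_from(basis[:, [0]])
        fp = w.fingerprints(wm, basis)
        assert fp.z[0, 0] == pytest.approx(np.arctanh(1 - FISHER_CLIP))
        assert np.all(np.abs(fp.z[0, 1:]) < fp.z[0, 0])

    def test_zero_correlation_maps_to_zero(self):
        t = np.arange(40)
        a = np.sin(2 * np.pi * t / 8)
        b = np.cos(2 * np.pi * t / 8)
        fp = w.fingerprints(series_from(a[:, None]), b[:, None])
        assert fp.z[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_half_correlation_matches_atanh_oracle(self, rng):
        # construct an exact r=0.5 pair
        x = rng.normal(size=500)
        e = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        y = 0.5 * x + np.sqrt(0.75) * e
        fp = w.fingerprints(series_from(y[:, None]), x[:, None])
        assert fp.z[0, 0] == pytest.approx(0.5493, abs=1e-4)


class TestEtaSquared:
    def test_identical_profiles_give_one(self):
        assert w.eta_squared([0.3, -1, 2], [0.3, -1, 2]) == 1.0

    def test_hand_computed_example(self):
        # SS_within = 4, SS_total = 5
        assert w.eta_squared([1, 2], [3, 0]) == pytest.approx(0.2)

    def test_symmetry_and_oracle_agreement(self, rng):
        for _ in range(100):
            a = rng.normal(size=7)
            b = rng.normal(size=7)
            ab = w.eta_squared(a, b)
            assert ab == pytest.approx(w.eta_squared(b, a), abs=1e-12)
            assert ab == pytest.approx(eta_squared_bruteforce(a, b), abs=1e-10)
            assert 0.0 <= ab <= 1.0

    def test_constant_pairs(self):
        # identical constants: zero total SS, similarity defined as 1
        assert w.eta_squared([1.0, 1.0], [1.0, 1.0]) == 1.0
        # different constants: all spread is between-profile, eta^2 = 0
        assert w.eta_squared([1.0, 1.0], [2.0, 2.0]) == pytest.approx(0.0)


class TestSimilarityMatrix:
    def _fp(self, z):
        z = np.asarray(z, dtype=float)
        vox = np.array([[i, 0, 0] for i in range(z.shape[0])])
        region = VoxelRegion(shape=(z.shape[0], 1, 1), affine=np.eye(4),
                             voxels=vox)
        return w.FingerprintMatrix(z=z, region=region,
                                   n_components=z.shape[1])

    def test_duplicated_rows_hit_unit_similarity(self, rng):
        z = rng.normal(size=(4, 10))
        z[2] = z[0]
        s = w.similarity_matrix(self._fp(z)).similarity
        assert s[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pairwise_bruteforce(self, rng):
        z = rng.normal(size=(30, 12))
        s = w.similarity_matrix(self._fp(z)).similarity
        for i in range(30):
            for j in range(i + 1, 30):
                assert s[i, j] == pytest.approx(
                    eta_squared_bruteforce(z[i], z[j]), abs=1e-10)

    def test_permutation_equivariance(self, rng):
        z = rng.normal(size=(15, 8))
        perm = rng.permutation(15)
        s = w.similarity_matrix(self._fp(z)).similarity
        sp_ = w.similarity_matrix(self._fp(z[perm])).similarity
        np.testing.assert_allclose(sp_, s[np.ix_(perm, perm)], atol=1e-12)


class TestGroupAverage:
    def test_single_subject_identity(self, rng):
        a = rng.normal(size=(6, 6))
        a = (a + a.T) / 2
        np.testing.assert_array_equal(w.group_average([a]), a)

    def test_matches_elementwise_mean_oracle(self, rng):
        mats = []
        for _ in range(5):
            m = rng.normal(size=(8, 8))
            mats.append((m + m.T) / 2)
        oracle = sum(mats) / 5
        np.testing.assert_allclose(w.group_average(mats), oracle, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        a = np.eye(3)
        with pytest.raises(ValueError):
            w.group_average([a, np.eye(4)])


def similarity_from_pairs(n, pairs, default=0.0):
    s = np.full((n, n), default)
    np.fill_diagonal(s, 1.0)
    for (i, j), v in pairs.items():
        s[i, j] = s[j, i] = v
    return s


class TestSparsifyConnected:
    def test_three_voxel_threshold_scan_oracle(self):
        s = similarity_from_pairs(3, {(0, 1): 0.9, (1, 2): 0.8, (0, 2): 0.1})
        graph = w.sparsify_connected(s)
        # exhaustive scan: smallest connecting epsilon is the 0.8 pair
        assert graph.epsilon == pytest.approx(np.sqrt(2 * (1 - 0.8)))
        adj = graph.adjacency.toarray()
        assert adj[0, 1] == pytest.approx(0.9)
        assert adj[1, 2] == pytest.approx(0.8)
        assert adj[0, 2] == 0.0

    def test_chain_similarity_yields_exact_chain(self, rng):
        # neighbor similarities high and decreasing, all others low
        n = 12
        neigh = {(i, i + 1): 0.95 - 0.01 * i for i in range(n - 1)}
        s = similarity_from_pairs(n, neigh, default=0.2)
        graph = w.sparsify_connected(s)
        adj = (graph.adjacency.toarray() > 0)
        oracle = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            oracle[i, i + 1] = oracle[i + 1, i] = True
        np.testing.assert_array_equal(adj, oracle)
        # union-find check: exactly one component at epsilon, none below
        assert graph.connected
        weakest = min(neigh.values())
        assert graph.epsilon == pytest.approx(np.sqrt(2 * (1 - weakest)))

    def test_minimal_epsilon_invariant_to_permutation(self, rng):
        m = rng.uniform(0.2, 0.9, size=(20, 20))
        s = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(s, 1.0)
        perm = rng.permutation(20)
        assert w.sparsify_connected(s).epsilon == pytest.approx(
            w.sparsify_connected(s[np.ix_(perm, perm)]).epsilon)

    def test_non_finite_rejected(self):
        s = np.eye(3)
        s[0, 1] = s[1, 0] = np.nan
        with pytest.raises(ValueError):
            w.sparsify_connected(s)


def graph_from_adjacency(adj):
    adj = np.asarray(adj, dtype=float)
    return SimilarityGraph(similarity=adj + np.eye(len(adj)),
                           adjacency=sp.csr_matrix(adj),
                           epsilon=1.0, connected=True)


class TestLaplacianEigenmaps:
    def test_path_graph_matches_dense_oracle(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        gs = w.laplacian_eigenmaps(graph_from_adjacency(adj), k=2)
        np.testing.assert_allclose(gs.eigenvalues, [1.0, 3.0], atol=1e-10)
        g1 = gs.gradients[:, 0]
        assert np.all(np.diff(g1) > 0) or np.all(np.diff(g1) < 0)

    def test_complete_graph_flagged_degenerate(self):
        adj = np.ones((5, 5)) - np.eye(5)
        gs = w.laplacian_eigenmaps(graph_from_adjacency(adj), k=2)
        assert gs.degenerate
        np.testing.assert_allclose(gs.eigenvalues, [5.0, 5.0], atol=1e-10)

    def test_sparse_solver_matches_dense_bruteforce(self, rng):
        # random connected weighted graph, <= 200 nodes
        n = 150
        s = np.clip(rng.uniform(0, 1, (n, n)), 0, 1)
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        graph = w.sparsify_connected(s)
        dense = w.laplacian_eigenmaps(graph, k=3, method="dense")
        sparse = w.laplacian_eigenmaps(graph, k=3, method="sparse")
        np.testing.assert_allclose(sparse.eigenvalues, dense.eigenvalues,
                                   rtol=1e-8)
        for j in range(3):
            cos = abs(sparse.gradients[:, j] @ dense.gradients[:, j])
            assert cos >= 1 - 1e-6

    def test_zero_mode_verified_and_discarded(self, small_gradients):
        gs = small_gradients
        assert gs.n_gradients == 3
        assert np.all(gs.eigenvalues > 0)
        assert np.all(np.diff(gs.eigenvalues) >= 0)
        assert np.all(gs.variance_explained >= 0)
        assert gs.variance_explained.sum() <= 1.0 + 1e-9
        # gradients mutually orthogonal
        gram = gs.gradients.T @ gs.gradients
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_disconnected_graph_rejected(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        with pytest.raises(ValueError):
            w.laplacian_eigenmaps(graph_from_adjacency(adj), k=1)

    def test_k_bounds(self):
        adj = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            w.laplacian_eigenmaps(graph_from_adjacency(adj), k=4)

    def test_noiseless_phantom_recovers_planted_axis(self, small_scene,
                                                     small_gradients):
        rho = spearmanr(small_gradients.gradients[:, 0],
                        small_scene.axis_positions[:, 0]).statistic
        assert abs(rho) >= 0.95


class TestAlignGradientSigns:
    def test_reference_equal_and_negated(self, small_gradients):
        gs = small_gradients
        same = w.align_gradient_signs(gs, gs.gradients)
        np.testing.assert_array_equal(same.gradients, gs.gradients)
        flipped = w.align_gradient_signs(gs, -gs.gradients)
        np.testing.assert_array_equal(flipped.gradients, -gs.gradients)

    def test_absolute_statistics_invariant(self, small_scene, small_gradients):
        gs = small_gradients
        ref = small_scene.axis_positions[:, :3]
        aligned = w.align_gradient_signs(gs, ref)
        for j in range(3):
            r_before = np.corrcoef(gs.gradients[:, j], ref[:, j])[0, 1]
            r_after = np.corrcoef(aligned.gradients[:, j], ref[:, j])[0, 1]
            assert abs(r_after) == pytest.approx(abs(r_before), abs=1e-12)
            assert r_after >= 0

    def test_zero_variance_reference_rejected(self, small_gradients):
        n = small_gradients.gradients.shape[0]
        with pytest.raises(ValueError):
            w.align_gradient_signs(small_gradients, np.ones(n))
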