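import numpy as np
import pytest

from metabotree.dimred import (
    TSNEConfig,
    kl_divergence,
    pca_fit,
    pca_transform,
    tsne_conditional_probs,
    tsne_embed,
    tsne_low_dim_affinities,
    tsne_symmetrize,
)
from metabotree.errors import ValidationError


class TestPCAFit:
    def test_collinear_data(self, rng):
        t = rng.normal(size=50)
        X = np.column_stack([t, t])
        model = pca_fit(X, 2)
        np.testing.assert_allclose(np.abs(model.components[0]), [1, 1] / np.sqrt(2), atol=1e-8)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(20, 5))
        model = pca_fit(X, 5)
        coords = pca_transform(model, X).coords
        back = coords @ model.components + model.mean
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_svd_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(50, 8))
            model = pca_fit(X, 8)
            # independent oracle: singular value decomposition of centered data
            centered = X - X.mean(axis=0)
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            np.testing.assert_allclose(model.eigenvalues, s**2 / (50 - 1), atol=1e-8)
            for i in range(8):
                dot = abs(np.dot(model.components[i], vt[i]))
                assert dot == pytest.approx(1.0, abs=1e-8)  # equal up to sign

    def test_sign_convention(self, rng):
        X = rng.normal(size=(30, 4))
        model = pca_fit(X, 4)
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_orthonormality(self, rng):
        model = pca_fit(rng.normal(size=(40, 6)), 4)
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(4), atol=1e-8
        )

    def test_n_components_validation(self, rng):
        with pytest.raises(ValidationError):
            pca_fit(rng.normal(size=(5, 3)), 4)


class TestPCATransform:
    def test_mean_maps_to_origin(self, rng):
        X = rng.normal(size=(25, 4))
        model = pca_fit(X, 3)
        coords = pca_transform(model, model.mean[None, :]).coords
        np.testing.assert_allclose(coords, 0, atol=1e-12)

    def test_projection_variance_equals_eigenvalues(self, rng):
        X = rng.normal(size=(60, 5))
        model = pca_fit(X, 5)
        coords = pca_transform(model, X).coords
        np.testing.assert_allclose(coords.var(axis=0, ddof=1), model.eigenvalues, atol=1e-8)

    def test_out_of_sample_no_refit(self, rng):
        X = rng.normal(size=(25, 4))
        model = pca_fit(X, 2)
        mean_before = model.mean.copy()
        pca_transform(model, rng.normal(size=(5, 4)))
        np.testing.assert_array_equal(model.mean, mean_before)

    def test_dimension_mismatch(self, rng):
        model = pca_fit(rng.normal(size=(10, 4)), 2)
        with pytest.raises(ValidationError):
            pca_transform(model, rng.normal(size=(3, 5)))


class TestConditionalProbs:
    def test_rows_sum_to_one_diagonal_zero(self, rng):
        P = tsne_conditional_probs(rng.normal(size=(12, 4)), 5.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (np.diag(P) == 0).all()

    def test_equilateral_triangle(self):
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        P = tsne_conditional_probs(X, 2.0)
        off = P[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-10)

    def test_perplexity_hits_target(self, rng):
        X = rng.normal(size=(20, 6))
        target = 7.0
        P = tsne_conditional_probs(X, target)
        for i in range(20):
            row = P[i][P[i] > 0]
            h = -np.sum(row * np.log2(row))  # direct entropy recomputation
            assert 2**h == pytest.approx(target, abs=1e-4)

    def test_perplexity_validation(self, rng):
        with pytest.raises(ValidationError):
            tsne_conditional_probs(rng.normal(size=(5, 2)), 5.0)
        with pytest.raises(ValidationError):
            tsne_conditional_probs(rng.normal(size=(2, 2)), 1.0)


class TestSymmetrize:
    def test_symmetric_input_fixed_point(self):
        n = 4
        P = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(P, 0.0)
        S = tsne_symmetrize(P)
        np.testing.assert_allclose(S, P / n, atol=1e-15)

    def test_exact_symmetry(self, rng):
        P = rng.random((8, 8))
        np.fill_diagonal(P, 0)
        P /= P.sum(axis=1, keepdims=True)
        S = tsne_symmetrize(P)
        np.testing.assert_array_equal(S, S.T)

    def test_unit_total_mass(self, rng):
        for _ in range(10):
            P = rng.random((9, 9))
            np.fill_diagonal(P, 0)
            P /= P.sum(axis=1, keepdims=True)
            assert tsne_symmetrize(P).sum() == pytest.approx(1.0, abs=1e-10)


class TestLowDimAffinities:
    def test_two_points(self, rng):
        Q = tsne_low_dim_affinities(rng.normal(size=(2, 2)))
        assert Q[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert Q[1, 0] == pytest.approx(0.5, abs=1e-12)

    def test_coincident_points_max_kernel(self):
        Y = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        d2_01 = 0.0
        assert 1.0 / (1.0 + d2_01) == 1.0  # kernel at distance 0 is maximal
        Q = tsne_low_dim_affinities(Y)
        assert Q[0, 1] == Q.max()

    def test_brute_force_double_loop(self, rng):
        Y = rng.normal(size=(15, 2))
        Q = tsne_low_dim_affinities(Y)
        total = 0.0
        for k in range(15):
            for l in range(15):
                if k != l:
                    total += 1.0 / (1.0 + np.sum((Y[k] - Y[l]) ** 2))
        expected = np.zeros((15, 15))
        for i in range(15):
            for j in range(15):
                if i != j:
                    expected[i, j] = 1.0 / (1.0 + np.sum((Y[i] - Y[j]) ** 2)) / total
        np.testing.assert_allclose(Q, expected, atol=1e-12)

    def test_unit_mass(self, rng):
        Q = tsne_low_dim_affinities(rng.normal(size=(11, 3)))
        assert Q.sum() == pytest.approx(1.0, abs=1e-10)


class TestKLDivergence:
    def _random_joint(self, rng, n=6):
        S = rng.random((n, n))
        np.fill_diagonal(S, 0)
        return S / S.sum()

    def test_identity_is_zero(self, rng):
        S = self._random_joint(rng)
        assert kl_divergence(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_non_negative(self, rng):
        for _ in range(10):
            assert kl_divergence(self._random_joint(rng), self._random_joint(rng)) >= 0

    def test_term_by_term_oracle(self, rng):
        S, Q = self._random_joint(rng), self._random_joint(rng)
        expected = 0.0
        for i in range(6):
            for j in range(6):
                if S[i, j] > 0:
                    expected += S[i, j] * np.log(S[i, j] / Q[i, j])
        assert kl_divergence(S, Q) == pytest.approx(expected, abs=1e-12)

    def test_zero_q_floored_with_warning(self, rng, caplog):
        S = self._random_joint(rng)
        Q = np.zeros_like(S)
        with caplog.at_level("WARNING"):
            v = kl_divergence(S, Q)
        assert np.isfinite(v) and "flooring" in caplog.text

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            kl_divergence(np.zeros((2, 2)), np.zeros((3, 3)))


@pytest.fixture(scope="module")
def clusters():
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.3, size=(10, 20))
    b = rng.normal(0.0, 0.3, size=(10, 20)) + 6.0
    return np.vstack([a, b]), np.array([0] * 10 + [1] * 10)


class TestEmbed:
    def test_cluster_recovery(self, clusters):
        X, labels = clusters
        emb = tsne_embed(X, TSNEConfig(out_dim=2, perplexity=5, n_iter=400, seed=3))
        Y = emb.coords
        centroids = np.array([Y[labels == c].mean(axis=0) for c in (0, 1)])
        assigned = np.argmin(
            np.linalg.norm(Y[:, None, :] - centroids[None], axis=2), axis=1
        )
        assert (assigned == labels).mean() == 1.0

    def test_seeded_determinism_bit_identical(self, clusters):
        X, _ = clusters
        cfg = TSNEConfig(out_dim=2, perplexity=5, n_iter=100, seed=11)
        a = tsne_embed(X, cfg)
        b = tsne_embed(X, cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.final_kl == b.final_kl

    def test_kl_descends_after_exaggeration(self, clusters):
        X, _ = clusters
        emb = tsne_embed(X, TSNEConfig(out_dim=2, perplexity=5, n_iter=400, seed=3))
        assert emb.final_kl <= emb.kl_history[50]
        assert emb.final_kl >= 0

    def test_default_perplexity_guard(self, rng):
        # N=10 -> default perplexity (N-1)/3 = 3, valid
        emb = tsne_embed(rng.normal(size=(10, 4)), TSNEConfig(out_dim=2, n_iter=20, seed=0))
        assert emb.coords.shape == (10, 2)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TSNEConfig(out_dim=4)
        with pytest.raises(ValidationError):
            TSNEConfig(perplexity=-1.0)
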