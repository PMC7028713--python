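"""Autoencoder, scaler, PCA baseline, greedy search and serialization."""
import numpy as np
import pytest
from numpy.linalg import svd

from gccscreen.exceptions import ConfigError, DomainError, TrainingError
from gccscreen.reduction import (DEFAULT_ARCH, FeatureScaler, SearchSpace,
                                 TrainConfig, fit_autoencoder, fit_pca,
                                 greedy_search, init_autoencoder, load_model,
                                 loss_and_grads, model_from_dict,
                                 model_to_dict, n_parameters, pca_score,
                                 save_model, train_autoencoder)


def numeric_gradients(model, S, eps=1e-5):
    """Central-difference oracle for the backprop gradients."""
    num_W, num_b = [], []
    for arrs, out in ((model.weights, num_W), (model.biases, num_b)):
        for A in arrs:
            G = np.zeros_like(A)
            it = np.nditer(A, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = A[ix]
                A[ix] = orig + eps
                lp, _, _ = loss_and_grads(model, S)
                A[ix] = orig - eps
                lm, _, _ = loss_and_grads(model, S)
                A[ix] = orig
                G[ix] = (lp - lm) / (2 * eps)
            out.append(G)
    return num_W, num_b


def max_rel_error(analytic, numeric):
    # entries far below the central-difference resolution are compared
    # against an absolute floor instead of a vanishing denominator
    worst = 0.0
    for A, N in zip(analytic, numeric):
        denom = np.maximum(1e-6, np.abs(A) + np.abs(N))
        worst = max(worst, float(np.max(np.abs(A - N) / denom)))
    return worst


class TestScaler:
    def test_affine_map_and_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(50, 10, size=(40, 4))
        X[:, 0] = np.linspace(0.0, 10.0, 40)
        scaler = FeatureScaler(lo=0.0, hi=1.0).fit(X)
        mid = scaler.transform(np.full((1, 4), 5.0))
        assert mid[0, 0] == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(X)), X, atol=1e-9)

    def test_out_of_range_values_extrapolate_not_clip(self):
        X = np.array([[0.0], [10.0]])
        scaler = FeatureScaler(lo=0.1, hi=0.9).fit(X)
        assert scaler.transform(np.array([[20.0]]))[0, 0] > 0.9

    def test_constant_feature_error_names_it(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(DomainError, match="whr"):
            FeatureScaler().fit(X, feature_names=["bmi", "whr"])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigError):
            FeatureScaler(lo=0.9, hi=0.1)


class TestBackprop:
    def test_gradients_match_central_differences(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(0.1, 0.9, size=(20, 10))
        model = init_autoencoder((10, 4, 1, 4, 10), "sigmoid", seed=2)
        _, gW, gb = loss_and_grads(model, S)
        num_W, num_b = numeric_gradients(model, S)
        assert max_rel_error(gW, num_W) < 1e-5
        assert max_rel_error(gb, num_b) < 1e-5

    def test_zero_learning_rate_is_a_no_op(self):
        rng = np.random.default_rng(2)
        S = rng.uniform(0.2, 0.8, size=(50, 10))
        cfg = TrainConfig(learning_rate=0.0, max_epochs=5, patience=10,
                          val_fraction=0.0, seed=0)
        model = train_autoencoder(S, DEFAULT_ARCH, cfg)
        ref = init_autoencoder(DEFAULT_ARCH, "sigmoid", seed=0)
        for W, W0 in zip(model.weights, ref.weights):
            np.testing.assert_array_equal(W, W0)
        assert len(set(np.round(model.loss_history, 15))) == 1

    def test_full_batch_descent_monotone_loss(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0.2, 0.8, size=(60, 10))
        cfg = TrainConfig(optimizer="sgd", momentum=0.0, learning_rate=0.05,
                          batch_size=60, max_epochs=60, patience=100,
                          val_fraction=0.0, seed=1)
        model = train_autoencoder(S, (10, 4, 1, 4, 10), cfg)
        diffs = np.diff(model.loss_history[:51])
        assert (diffs <= 1e-12).all()

    def test_unscaled_input_rejected_for_sigmoid(self):
        with pytest.raises(DomainError):
            train_autoencoder(np.random.default_rng(0).normal(size=(30, 10)),
                              DEFAULT_ARCH, TrainConfig(max_epochs=1))


class TestTraining:
    def test_training_reduces_mse_below_untrained(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        cfg = TrainConfig(seed=0, max_epochs=100)
        model = fit_autoencoder(X, DEFAULT_ARCH, cfg)
        untrained = init_autoencoder(DEFAULT_ARCH, "sigmoid", seed=99)
        untrained.scaler = model.scaler
        _, mse_trained = model.reconstruct(X)
        _, mse_untrained = untrained.reconstruct(X)
        assert mse_trained.mean() < mse_untrained.mean()
        assert model.loss_history[-1] <= model.loss_history[0]

    def test_loss_history_final_entry_matches_reconstruction(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        cfg = TrainConfig(seed=1, max_epochs=40, val_fraction=0.0)
        model = fit_autoencoder(X, DEFAULT_ARCH, cfg)
        _, per_row = model.reconstruct(X)
        assert per_row.mean() == pytest.approx(model.loss_history[-1], abs=1e-8)

    def test_one_dimensional_manifold_reconstructed_to_noise_floor(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.0, 1.0, size=(200, 1))
        a = rng.uniform(0.2, 0.4, 10)
        b = rng.uniform(0.3, 0.5, 10)
        noise_sd = 0.02
        S = a + t * b + rng.normal(0, noise_sd, size=(200, 10))
        S = np.clip(S, 0.01, 0.99)
        cfg = TrainConfig(seed=2, max_epochs=400, patience=60, val_fraction=0.0)
        model = train_autoencoder(S, (10, 4, 1, 4, 10), cfg)
        assert model.loss_history[-1] < 2 * noise_sd ** 2

    def test_encoded_scores_in_unit_interval_and_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        model = fit_autoencoder(X, DEFAULT_ARCH, TrainConfig(seed=3, max_epochs=50))
        s = model.encode(X)
        assert ((s > 0) & (s < 1)).all() and np.isfinite(s).all()
        dup = np.vstack([X[:1], X[:1]])
        sd = model.encode(dup)
        assert sd[0] == sd[1]

    def test_wrong_column_count_is_shape_error(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        model = fit_autoencoder(X, DEFAULT_ARCH, TrainConfig(seed=0, max_epochs=2))
        with pytest.raises(ConfigError):
            model.encode(X[:, :7])

    def test_divergence_reported_with_epoch_and_rate(self):
        # a linear network with an absurd learning rate blows up; the
        # sigmoid variant cannot (its loss is bounded by construction)
        rng = np.random.default_rng(5)
        S = rng.uniform(0.2, 0.8, size=(40, 10)) * 100
        cfg = TrainConfig(optimizer="sgd", learning_rate=1e3, max_epochs=50,
                          val_fraction=0.0, seed=0)
        with pytest.raises(TrainingError, match="learning rate"):
            train_autoencoder(S, (10, 4, 1, 4, 10), cfg, activation="identity")


class TestLinearLimit:
    """With identity activations an autoencoder's optimum is the principal
    subspace (the classic PCA limit), giving an external oracle via SVD."""

    def _angle(self, u, v):
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        return np.degrees(np.arccos(min(1.0, abs(float(u @ v)))))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bottleneck_direction_matches_first_singular_vector(self, seed):
        rng = np.random.default_rng(seed)
        _, _, Vt = svd(rng.standard_normal((200, 10)), full_matrices=False)
        X = (rng.standard_normal((400, 1)) * 3.0) @ Vt[:1] \
            + rng.standard_normal((400, 10)) * 0.3
        cfg = TrainConfig(seed=seed, max_epochs=500, patience=50,
                          val_fraction=0.0)
        model = train_autoencoder(X, (10, 1, 10), cfg, activation="identity")
        w = model.weights[0][:, 0]
        v1 = svd(X - X.mean(axis=0), full_matrices=False)[2][0]
        assert self._angle(w, v1) < 5.0

    def test_bottleneck_two_recovers_top_two_subspace(self):
        rng = np.random.default_rng(7)
        _, _, Vt = svd(rng.standard_normal((200, 10)), full_matrices=False)
        Z = rng.standard_normal((400, 2)) * np.array([3.0, 2.0])
        X = Z @ Vt[:2] + rng.standard_normal((400, 10)) * 0.2
        cfg = TrainConfig(seed=7, max_epochs=500, patience=50, val_fraction=0.0)
        model = train_autoencoder(X, (10, 2, 10), cfg, activation="identity")
        W = model.weights[0]  # 10 x 2 encoder map
        V = svd(X - X.mean(axis=0), full_matrices=False)[2][:2].T  # 10 x 2
        qw, _ = np.linalg.qr(W)
        qv, _ = np.linalg.qr(V)
        angles = np.degrees(np.arccos(np.clip(
            svd(qw.T @ qv, compute_uv=False), -1, 1)))
        assert angles.max() < 5.0


class TestPCA:
    def test_collinear_data_first_component_explains_all(self):
        t = np.linspace(0, 1, 50)[:, None]
        X = t @ np.array([[2.0, -1.0]])
        model = fit_pca(X)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal([0, 0, 0], [[3, 1, 0], [1, 2, 0.5],
                                                [0, 0.5, 1]], size=300)
        model = fit_pca(X)
        cov = np.cov(X, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        for k in range(3):
            v = vecs[:, order[k]]
            assert abs(float(model.components[k] @ v)) == pytest.approx(1.0, abs=1e-8)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_scores_equivariant_under_rotation(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 5)) * np.array([3, 1, 1, 0.5, 0.2])
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        s1 = pca_score(fit_pca(X), X)
        s2 = pca_score(fit_pca(X @ Q), X @ Q)
        r = np.corrcoef(s1, s2)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_k_out_of_range_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 4))
        with pytest.raises(ConfigError):
            pca_score(fit_pca(X), X, k=11)


class TestGreedySearch:
    def _data(self, n=400):
        rng = np.random.default_rng(10)
        t = rng.uniform(0, 1, size=(n, 1))
        return np.clip(0.3 + t @ rng.uniform(0.2, 0.4, (1, 10))
                       + rng.normal(0, 0.03, (n, 10)), 0.02, 0.98)

    def test_single_candidate_space_returned(self):
        S = self._data()
        space = SearchSpace(depths=(2,), first_widths=(8,),
                            learning_rates=(0.01,), batch_sizes=(32,))
        widths, cfg, log = greedy_search(
            S, space, TrainConfig(max_epochs=30), seed=0)
        assert widths == space.architecture(2, 8)
        assert cfg.learning_rate == 0.01 and cfg.batch_size == 32

    def test_clearly_dominant_candidate_wins(self):
        S = self._data()
        space = SearchSpace(depths=(1,), first_widths=(6,),
                            learning_rates=(1e-7, 0.01), batch_sizes=(32,))
        widths, cfg, log = greedy_search(
            S, space, TrainConfig(max_epochs=40), seed=0)
        assert cfg.learning_rate == 0.01

    def test_deterministic_given_seed(self):
        S = self._data()
        space = SearchSpace(depths=(1, 2), first_widths=(6, 8),
                            learning_rates=(0.01,), batch_sizes=(32, 64))
        out1 = greedy_search(S, space, TrainConfig(max_epochs=20), seed=5)
        out2 = greedy_search(S, space, TrainConfig(max_epochs=20), seed=5)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_degrees_of_freedom_guard_skips_oversized(self):
        S = self._data(n=40)
        space = SearchSpace(depths=(3,), first_widths=(12,),
                            learning_rates=(0.01,), batch_sizes=(16,))
        # 10-12-6-3-1-... has far more than 40 parameters
        assert n_parameters(space.architecture(3, 12)) >= 32
        with pytest.raises(TrainingError):
            greedy_search(S, space, TrainConfig(max_epochs=5), seed=0)

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigError):
            greedy_search(self._data(), SearchSpace(depths=()), seed=0)


class TestSerialization:
    def test_round_trip_reproduces_scores_exactly(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        model = fit_autoencoder(X, DEFAULT_ARCH, TrainConfig(seed=4, max_epochs=30))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.encode(X), model.encode(X),
                                   rtol=0, atol=1e-12)

    def test_dict_round_trip_preserves_structure(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.biomarkers().to_numpy()
        model = fit_autoencoder(X, DEFAULT_ARCH, TrainConfig(seed=5, max_epochs=5))
        back = model_from_dict(model_to_dict(model))
        assert back.widths == model.widths
        assert back.activation == model.activation
        np.testing.assert_array_equal(back.scaler.mins, model.scaler.mins)
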