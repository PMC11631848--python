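"""Learned-operator tests: normalization, loss, scaling, shapes, training."""

import numpy as np
import pytest

import stesi
from stesi.data import generate_dataset
from stesi.networks import ArchitectureSpec, Model, TrainConfig, _cosine_loss_ad


class TestNormalizePair:
    def test_divides_by_max_abs(self, rng):
        X = rng.standard_normal((5, 8))
        Y = rng.standard_normal((3, 8))
        Y[1, 2] = -2.0  # ensure known max
        Y = np.clip(Y, -2.0, 2.0)
        pair = stesi.normalize_pair(X, Y)
        assert np.max(np.abs(pair.Y_tilde)) == pytest.approx(1.0)
        assert pair.alpha == pytest.approx(2.0)
        assert np.allclose(pair.X_tilde, X / 2.0)

    def test_idempotent_on_normalized_input(self, rng):
        Y = rng.uniform(-1, 1, (3, 6))
        Y[0, 0] = 1.0
        X = rng.standard_normal((4, 6))
        pair = stesi.normalize_pair(X, Y)
        assert pair.alpha == 1.0
        assert np.array_equal(pair.Y_tilde, Y)

    def test_preserves_forward_linearity(self, toy_head):
        cfg = stesi.SereegaConfig(duration=0.2, snr_db=300.0)
        s = stesi.simulate_sample_sereega(toy_head, cfg,
                                          np.random.default_rng(0))
        pair = stesi.normalize_pair(s.X, s.Y_clean)
        assert np.allclose(toy_head.leadfield_regional @ pair.X_tilde,
                           pair.Y_tilde, rtol=1e-12, atol=1e-25)

    def test_zero_eeg_rejected(self):
        with pytest.raises(ValueError):
            stesi.normalize_pair(np.ones((2, 3)), np.zeros((2, 3)))


class TestCosineLoss:
    def test_identity_is_minus_one(self, rng):
        X = rng.standard_normal((6, 10))
        assert stesi.cosine_loss(X, X) == pytest.approx(-1.0)

    def test_positive_scaling_invariance(self, rng):
        X = rng.standard_normal((6, 10))
        for c in (0.01, 3.0, 1e6):
            assert stesi.cosine_loss(X, c * X) == pytest.approx(-1.0)

    def test_orthogonal_columns_zero(self):
        X = np.zeros((4, 3))
        X[0] = 1.0
        Xh = np.zeros((4, 3))
        Xh[1] = 1.0
        assert stesi.cosine_loss(X, Xh) == pytest.approx(0.0)

    def test_bounded(self, rng):
        for _ in range(20):
            X = rng.standard_normal((5, 7))
            Xh = rng.standard_normal((5, 7))
            assert -1.0 <= stesi.cosine_loss(X, Xh) <= 1.0

    def test_guarded_columns_counted(self, rng):
        X = rng.standard_normal((4, 5))
        X[:, 2] = 0.0
        loss, guarded = stesi.cosine_loss(X, X, return_guarded=True)
        assert guarded == 1
        assert loss == pytest.approx(-4.0 / 5.0)

    def test_autodiff_version_matches_numpy(self, rng):
        X = rng.standard_normal((2, 5, 7))
        Xh = rng.standard_normal((2, 5, 7))
        from stesi.autodiff import Tensor
        ad = _cosine_loss_ad(Tensor(Xh), X).item()
        ref = np.mean([stesi.cosine_loss(X[b], Xh[b]) for b in range(2)])
        assert ad == pytest.approx(ref)


class TestGFPRescale:
    def test_recovers_scaled_truth(self, toy_head, rng):
        L = toy_head.leadfield_regional
        X = np.zeros((50, 12))
        X[9] = rng.standard_normal(12) + 3.0
        Y = L @ X
        X_hat, flagged = stesi.gfp_rescale(X / 7.5, Y, L)
        assert np.allclose(X_hat, X, rtol=1e-10)
        assert not flagged

    def test_reprojected_std_matches(self, toy_head, rng):
        L = toy_head.leadfield_regional
        Y = rng.standard_normal((32, 6))
        Xt = rng.standard_normal((50, 6))
        X_hat, _ = stesi.gfp_rescale(Xt, Y, L)
        assert np.allclose((L @ X_hat).std(axis=0), Y.std(axis=0), rtol=1e-10)

    def test_idempotent(self, toy_head, rng):
        L = toy_head.leadfield_regional
        Y = rng.standard_normal((32, 6))
        Xt = rng.standard_normal((50, 6))
        once, _ = stesi.gfp_rescale(Xt, Y, L)
        twice, _ = stesi.gfp_rescale(once, Y, L)
        assert np.allclose(once, twice, rtol=1e-12)

    def test_zero_variance_column_flagged(self, toy_head):
        L = toy_head.leadfield_regional
        Y = np.ones((32, 3))
        Xt = np.zeros((50, 3))
        X_hat, flagged = stesi.gfp_rescale(Xt, Y, L)
        assert flagged == [0, 1, 2]
        assert np.array_equal(X_hat, Xt)


class TestArchitectures:
    @pytest.mark.parametrize("kind,kw", [
        ("cnn1d", dict(cnn_filters=16)),
        ("lstm", dict(lstm_hidden=8)),
        ("deepsif", dict(deepsif_feature_dim=12)),
    ])
    @pytest.mark.parametrize("T", [20, 50])
    def test_output_shape(self, kind, kw, T, rng):
        spec = ArchitectureSpec(kind=kind, n_electrodes=7, n_sources=9, **kw)
        model = stesi.build_model(spec, rng_seed=0)
        out = model.forward(rng.standard_normal((2, 7, T)))
        assert out.shape == (2, 9, T)

    def test_deepsif_spatial_dim(self, rng):
        spec = ArchitectureSpec(kind="deepsif", n_electrodes=7, n_sources=9,
                                deepsif_feature_dim=12)
        model = Model(spec, rng_seed=0)
        assert model.mid.W.shape == (12, 12)

    def test_cnn_rejects_short_window(self, rng):
        spec = ArchitectureSpec(kind="cnn1d", n_electrodes=4, n_sources=5,
                                cnn_filters=8)
        model = Model(spec, rng_seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((1, 4, 3)))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(kind="mlp", n_electrodes=4, n_sources=5)
        with pytest.raises(ValueError):
            ArchitectureSpec(kind="lstm", n_electrodes=4, n_sources=5,
                             lstm_dropout=1.0)


@pytest.fixture(scope="module")
def small_dataset(toy_head):
    cfg = stesi.SereegaConfig(rng_seed=3, duration=0.2, order_range=(1, 2))
    return generate_dataset(toy_head, cfg, 40, split=0.8)


class TestTraining:
    def test_overfit_small_cnn(self, toy_head, small_dataset):
        # capacity/optimization sanity: 32 training samples must be nearly
        # memorized within 200 epochs
        spec = ArchitectureSpec(kind="cnn1d", n_electrodes=32, n_sources=50,
                                cnn_filters=64)
        model = stesi.build_model(spec, rng_seed=0)
        cfg = TrainConfig(max_epochs=200, early_stop_patience=199,
                          learning_rate=3e-3, rng_seed=0)
        model, hist = stesi.train(model, small_dataset, cfg)
        assert min(hist["train_loss"]) <= -0.95

    def test_early_stopping_triggers_after_patience(self, toy_head,
                                                    small_dataset):
        # learning rate zero: validation loss never improves after epoch 0
        spec = ArchitectureSpec(kind="cnn1d", n_electrodes=32, n_sources=50,
                                cnn_filters=8)
        model = stesi.build_model(spec, rng_seed=0)
        cfg = TrainConfig(max_epochs=50, early_stop_patience=3,
                          learning_rate=0.0, rng_seed=0)
        model, hist = stesi.train(model, small_dataset, cfg)
        assert hist["epochs_run"] == 4  # epoch 0 improves from +inf, then 3 stale

    def test_deterministic_given_seed(self, toy_head, small_dataset):
        losses = []
        for _ in range(2):
            spec = ArchitectureSpec(kind="cnn1d", n_electrodes=32,
                                    n_sources=50, cnn_filters=16)
            model = stesi.build_model(spec, rng_seed=5)
            cfg = TrainConfig(max_epochs=3, early_stop_patience=2, rng_seed=5)
            _, hist = stesi.train(model, small_dataset, cfg)
            losses.append(hist["train_loss"])
        assert losses[0] == losses[1]

    def test_invalid_patience(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, early_stop_patience=10)


class TestPredict:
    def test_zero_input_guarded(self, toy_head):
        spec = ArchitectureSpec(kind="cnn1d", n_electrodes=32, n_sources=50,
                                cnn_filters=8)
        model = Model(spec, rng_seed=0)
        sol = stesi.predict(model, np.zeros((32, 20)),
                            toy_head.leadfield_regional)
        assert not sol.X_hat.any()
        assert sol.config.get("degenerate")

    def test_output_shape_and_gfp_consistency(self, toy_head, rng):
        spec = ArchitectureSpec(kind="cnn1d", n_electrodes=32, n_sources=50,
                                cnn_filters=8)
        model = Model(spec, rng_seed=0)
        Y = rng.standard_normal((32, 25))
        sol = stesi.predict(model, Y, toy_head.leadfield_regional)
        assert sol.X_hat.shape == (50, 25)
        proj = toy_head.leadfield_regional @ sol.X_hat
        ok = proj.std(axis=0) > 0
        assert np.allclose(proj.std(axis=0)[ok], Y.std(axis=0)[ok], rtol=1e-5)
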