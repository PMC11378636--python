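"""Autoencoder, weight transfer, and prediction-network behavior."""

import numpy as np
import pytest

from transcell._nn import LEAKY, IDENTITY, MLP
from transcell.networks import (
    AutoencoderSpec,
    EncoderState,
    TrainConfig,
    TransCellClassifier,
    TransCellRegressor,
    build_predictor,
    fit_predictor,
    init_autoencoder,
    make_encoder_variant,
    predict,
    reconstruction_loss,
    train_autoencoder,
    transfer_encoder_weights,
    two_step_pretrain,
)


@pytest.fixture(scope="module")
def factor_data():
    """Rank-3 latent data: n=200, m=30."""
    rng = np.random.default_rng(42)
    Z = rng.standard_normal((200, 3))
    L = rng.normal(size=(30, 3))
    return Z @ L.T + 0.3 * rng.standard_normal((200, 30))


class TestReconstructionLoss:
    def test_zero_for_perfect_reconstruction(self, rng):
        X = rng.normal(size=(5, 4))
        assert reconstruction_loss(X, X) == 0.0

    def test_single_squared_difference(self):
        assert reconstruction_loss([[1.0, 0.0]], [[0.0, 0.0]]) == 1.0

    def test_hand_arithmetic(self):
        X = [[1.0, 2.0], [3.0, 4.0]]
        X_hat = [[0.0, 2.0], [3.0, 6.0]]
        assert reconstruction_loss(X, X_hat) == pytest.approx(2.5)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss(np.ones((2, 2)), np.ones((2, 3)))

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(8, 5))
        X_hat = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        assert reconstruction_loss(X, X_hat) == pytest.approx(
            reconstruction_loss(X[perm], X_hat[perm])
        )

    def test_feature_duplication_doubles_loss(self, rng):
        X = rng.normal(size=(6, 4))
        X_hat = rng.normal(size=(6, 4))
        doubled = reconstruction_loss(np.hstack([X, X]), np.hstack([X_hat, X_hat]))
        assert doubled == pytest.approx(2 * reconstruction_loss(X, X_hat))


class TestSpecValidation:
    def test_dims_must_taper(self):
        with pytest.raises(ValueError):
            AutoencoderSpec(10, 12, 4)
        with pytest.raises(ValueError):
            AutoencoderSpec(10, 8, 0)

    def test_production_shapes(self):
        spec = AutoencoderSpec()
        assert spec.encoder_dims == [5000, 512, 200]
        assert spec.decoder_dims == [200, 512, 5000]


class TestTrainAutoencoder:
    def test_zero_epochs_is_identity_on_init(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        init = init_autoencoder(spec, seed=9)
        out = train_autoencoder(
            factor_data, spec, init=init, config=TrainConfig(epochs=0)
        )
        for (W0, _), (W1, _) in zip(init.encoder_layers, out.encoder_layers):
            assert np.array_equal(W0, W1)
        assert len(out.history) == 1  # epoch-0 evaluation recorded

    def test_training_beats_untrained_init(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        out = train_autoencoder(factor_data, spec, config=TrainConfig(epochs=60, seed=0))
        hist = out.history[-1]
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert hist["best_val_loss"] < hist["val_loss"][0]

    def test_wrong_column_count_errors(self, factor_data):
        with pytest.raises(ValueError, match="columns"):
            train_autoencoder(factor_data, AutoencoderSpec(31, 12, 6))

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="10 samples"):
            train_autoencoder(np.ones((5, 30)), AutoencoderSpec(30, 12, 6))

    def test_seeded_determinism(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        cfg = TrainConfig(epochs=8, seed=5)
        a = train_autoencoder(factor_data, spec, config=cfg)
        b = train_autoencoder(factor_data, spec, config=cfg)
        assert a.history[-1]["val_loss"] == b.history[-1]["val_loss"]
        assert np.array_equal(a.encoder_layers[0][0], b.encoder_layers[0][0])


class TestWeightTransfer:
    def test_transfer_is_bit_identical(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        src = train_autoencoder(factor_data, spec, config=TrainConfig(epochs=5, seed=1))
        init = transfer_encoder_weights(src, spec, seed=2)
        for (W0, b0), (W1, b1) in zip(src.encoder_layers, init.encoder_layers):
            assert np.array_equal(W0, W1) and np.array_equal(b0, b1)
        # decoder freshly re-initialized, not copied
        assert not np.array_equal(src.decoder_layers[0][0], init.decoder_layers[0][0])

    def test_zero_epoch_two_step_returns_source_encoder(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        cfg = TrainConfig(epochs=0, seed=1)
        src = train_autoencoder(factor_data, spec, config=TrainConfig(epochs=5, seed=1))
        enc = two_step_pretrain(factor_data, factor_data[:50], spec, config=cfg)
        # with a zero-epoch target budget the transferred weights are returned
        # unchanged except for the independently trained source phase
        assert enc.provenance == "two_step"
        src0 = train_autoencoder(factor_data, spec, config=TrainConfig(epochs=0, seed=1))
        assert enc.layers[0][0].shape == src0.encoder_layers[0][0].shape

    def test_gene_order_mismatch_errors(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        with pytest.raises(ValueError, match="mismatch"):
            two_step_pretrain(factor_data, factor_data[:, :29], spec)

    def test_production_weight_shapes(self):
        spec = AutoencoderSpec()  # 5000/512/200
        ae = init_autoencoder(spec, seed=0)
        assert ae.encoder_layers[0][0].shape == (5000, 512)
        assert ae.encoder_layers[1][0].shape == (512, 200)


@pytest.fixture(scope="module")
def variants(factor_data):
    spec = AutoencoderSpec(30, 12, 6)
    cfg = TrainConfig(epochs=4, seed=0)
    src, tgt = factor_data[:150], factor_data[150:]
    return {
        v: make_encoder_variant(src, tgt, spec, v, cfg)
        for v in ("two_step", "target_only", "source_only")
    }


class TestEncoderVariants:

    def test_provenance_tags(self, variants):
        for name, enc in variants.items():
            assert enc.provenance == name

    def test_source_only_has_single_training_phase(self, variants):
        assert [h["phase"] for h in variants["source_only"].history] == ["source_only"]

    def test_two_step_history_has_source_and_target_phases(self, variants):
        phases = [h["phase"] for h in variants["two_step"].history]
        assert phases[0] == "source" and phases[-1] == "target"

    def test_identical_layer_shapes_across_variants(self, variants):
        shapes = {
            name: [W.shape for W, _ in enc.layers] for name, enc in variants.items()
        }
        assert shapes["two_step"] == shapes["target_only"] == shapes["source_only"]


@pytest.fixture(scope="module")
def encoder():
    spec = AutoencoderSpec(30, 12, 6)
    return EncoderState(spec, init_autoencoder(spec, seed=2).encoder_layers, "target_only")


class TestPredictor:

    def test_head_input_matches_bottleneck(self, encoder):
        state = build_predictor(encoder, "regression")
        assert state.head_dims[0] == 6

    def test_encoder_carried_over_unchanged(self, encoder):
        state = build_predictor(encoder, "regression")
        for (W0, _), (W1, _) in zip(encoder.layers, state.encoder.layers):
            assert np.array_equal(W0, W1)

    def test_classification_outputs_probabilities(self, encoder, rng):
        state = build_predictor(encoder, "classification")
        p = predict(state, rng.normal(size=(20, 30)))
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_epoch_finetune_is_noop(self, encoder, rng):
        state = build_predictor(encoder, "regression")
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        out = fit_predictor(state, X, y, config=TrainConfig(epochs=0))
        for (W0, _), (W1, _) in zip(state.encoder.layers, out.encoder.layers):
            assert np.array_equal(W0, W1)
        for (W0, _), (W1, _) in zip(state.head_layers, out.head_layers):
            assert np.array_equal(W0, W1)

    def test_fit_beats_intercept_baseline(self, factor_data):
        spec = AutoencoderSpec(30, 12, 6)
        encoder = EncoderState(spec, init_autoencoder(spec, seed=3).encoder_layers, "target_only")
        y = factor_data[:, :3] @ np.array([1.0, -2.0, 0.5])
        state = build_predictor(encoder, "regression", {"hidden": (16, 8)})
        out = fit_predictor(state, factor_data, y, config=TrainConfig(epochs=120, seed=0))
        train_mse = np.mean((predict(out, factor_data) - y) ** 2)
        assert train_mse < y.var()

    def test_frozen_encoder_untouched(self, encoder, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        state = build_predictor(encoder, "regression")
        out = fit_predictor(
            state, X, y, config=TrainConfig(epochs=5), freeze_encoder=True
        )
        for (W0, _), (W1, _) in zip(state.encoder.layers, out.encoder.layers):
            assert np.array_equal(W0, W1)

    def test_single_class_classification_errors(self, encoder, rng):
        state = build_predictor(encoder, "classification")
        with pytest.raises(ValueError, match="both classes"):
            fit_predictor(state, rng.normal(size=(20, 30)), np.zeros(20))

    def test_duplicate_rows_predict_identically(self, encoder, rng):
        state = build_predictor(encoder, "regression")
        x = rng.normal(size=(1, 30))
        p = predict(state, np.vstack([x, x]))
        assert p[0] == p[1]

    def test_column_mismatch_errors(self, encoder, rng):
        state = build_predictor(encoder, "regression")
        with pytest.raises(ValueError, match="columns"):
            predict(state, rng.normal(size=(3, 29)))


class TestHandComputedForward:
    def test_leaky_relu_algebra(self):
        """2/2/1 network with hand-set weights on X=[[1,1]], alpha=0.1."""
        mlp = MLP([2, 2, 1], [LEAKY, IDENTITY], alpha=0.1, rng=np.random.default_rng(0))
        W1 = np.array([[1.0, -1.0], [1.0, -1.0]])  # z1 = [2, -2]
        b1 = np.zeros(2)
        W2 = np.array([[0.5], [1.0]])
        b2 = np.array([0.25])
        mlp.set_weights([[W1, b1], [W2, b2]])
        # a1 = [2, -0.2]; out = 2*0.5 + (-0.2)*1 + 0.25 = 1.05
        out = mlp.forward(np.array([[1.0, 1.0]]))
        assert out[0, 0] == pytest.approx(1.05)


class TestEstimators:
    def test_regressor_get_set_params_round_trip(self):
        m = TransCellRegressor(epochs=7, lr=0.01)
        params = m.get_params()
        assert params["epochs"] == 7
        m2 = TransCellRegressor().set_params(**params)
        assert m2.lr == 0.01

    def test_classifier_predict_proba_shape(self, rng):
        X = rng.normal(size=(60, 12))
        y = (X[:, 0] > 0).astype(float)
        m = TransCellClassifier(
            hidden_dim=8, bottleneck_dim=4, head_hidden=(6, 3), epochs=30, random_state=0
        ).fit(X, y)
        proba = m.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(m.predict(X))) <= {0.0, 1.0}
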