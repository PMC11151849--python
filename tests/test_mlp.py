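"""The tanh-hidden-layer surrogate network: init, forward pass, training, metrics."""

import dataclasses

import numpy as np
import pytest

from mycorun import (
    MLPModel,
    TrainConfig,
    compute_metrics,
    fit_surrogate,
    load_model,
    save_model,
    train_mlp,
)
from mycorun.mlp import init_mlp, mlp_forward


class TestInit:
    def test_deterministic_per_seed(self):
        a, b = init_mlp(4, 6, seed=3), init_mlp(4, 6, seed=3)
        np.testing.assert_array_equal(a.W1, b.W1)
        assert not np.allclose(a.W1, init_mlp(4, 6, seed=4).W1)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_mlp(4, 0, seed=0)
        with pytest.raises(ValueError):
            init_mlp(0, 3, seed=0)

    def test_init_spread_shrinks_with_width(self):
        narrow = np.std([init_mlp(4, 2, seed=s).W1 for s in range(200)])
        wide = np.std([init_mlp(4, 50, seed=s).W1 for s in range(200)])
        assert wide < narrow  # Xavier bound sqrt(6/(fan_in+fan_out)) decreases


class TestForward:
    def test_hand_computed_2_2_1_network(self):
        m = MLPModel(
            n_inputs=2, n_hidden=2,
            W1=np.array([[1.0, -1.0], [0.5, 0.5]]),
            b1=np.array([0.0, 0.1]),
            w2=np.array([2.0, -1.0]),
            b2=0.25,
        )
        x = np.array([[0.3, 0.2]])
        h = np.tanh([0.3 - 0.2, 0.5 * 0.3 + 0.5 * 0.2 + 0.1])
        expected = 2.0 * h[0] - 1.0 * h[1] + 0.25
        assert mlp_forward(m, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_weights_output_bias(self):
        m = MLPModel(3, 2, np.zeros((2, 3)), np.zeros(2), np.zeros(2), b2=0.7)
        np.testing.assert_allclose(mlp_forward(m, np.zeros((5, 3))), 0.7)

    def test_shape_mismatch(self):
        m = init_mlp(3, 2, seed=0)
        with pytest.raises(ValueError):
            mlp_forward(m, np.zeros((4, 2)))


class TestTraining:
    def test_linear_target_fit_nearly_exact(self, rng):
        X = rng.uniform(-1, 1, size=(400, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.3
        model = init_mlp(3, 4, seed=0)
        trained, _ = train_mlp(model, X, y, TrainConfig(seed=0, max_epochs=3000, patience=300))
        assert compute_metrics(y, mlp_forward(trained, X)).r2 > 0.999

    def test_nonlinear_toy_surface_capacity(self, rng):
        X = rng.uniform(-1, 1, size=(500, 2))
        y = np.sin(2.5 * X[:, 0]) * np.cos(1.5 * X[:, 1])
        big, _ = train_mlp(init_mlp(2, 12, seed=0), X, y, TrainConfig(seed=0, max_epochs=4000, patience=400))
        small, _ = train_mlp(init_mlp(2, 1, seed=0), X, y, TrainConfig(seed=0, max_epochs=4000, patience=400))
        r2_big = compute_metrics(y, mlp_forward(big, X)).r2
        r2_small = compute_metrics(y, mlp_forward(small, X)).r2
        assert r2_big > 0.98
        assert r2_small < r2_big  # capacity ordering on a nonlinear truth

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        X = rng.uniform(-1, 1, size=(50, 3))
        y = X.sum(axis=1)
        model = init_mlp(3, 4, seed=0)
        trained, history = train_mlp(model, X, y, dataclasses.replace(TrainConfig(), max_epochs=0))
        assert history == []
        np.testing.assert_array_equal(trained.W1, model.W1)

    def test_training_never_worsens_training_mse(self, rng):
        X = rng.uniform(-1, 1, size=(200, 3))
        y = X @ [0.5, 1.0, -1.0] + rng.normal(0, 0.05, 200)
        model = init_mlp(3, 5, seed=2)
        initial = float(np.mean((mlp_forward(model, X) - y) ** 2))
        trained, history = train_mlp(model, X, y, TrainConfig(seed=2, max_epochs=500))
        final = float(np.mean((mlp_forward(trained, X) - y) ** 2))
        assert final <= initial
        assert np.min(np.minimum.accumulate(history)) == min(history)

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(-1, 1, size=(100, 3))
        y = X.sum(axis=1)
        a, _ = train_mlp(init_mlp(3, 4, seed=1), X, y, TrainConfig(seed=1, max_epochs=200))
        b, _ = train_mlp(init_mlp(3, 4, seed=1), X, y, TrainConfig(seed=1, max_epochs=200))
        np.testing.assert_array_equal(a.W1, b.W1)


class TestMetrics:
    def test_perfect_and_null_predictions(self, rng):
        y = rng.uniform(1, 5, size=100)
        perfect = compute_metrics(y, y)
        assert (perfect.r2, perfect.rmse, perfect.mae, perfect.mape) == (1.0, 0.0, 0.0, 0.0)
        null = compute_metrics(y, np.full_like(y, y.mean()))
        assert null.r2 == pytest.approx(0.0, abs=1e-12)

    def test_mape_skips_zero_targets(self):
        m = compute_metrics(np.array([0.0, 2.0, 4.0]), np.array([1.0, 1.0, 2.0]))
        assert m.mape == pytest.approx((0.5 + 0.5) / 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(3), np.ones(4))


class TestEndToEnd:
    def test_prediction_in_original_units(self, rr_xy):
        X, y, feats = rr_xy
        model = fit_surrogate(X, y, 4, TrainConfig(seed=0, max_epochs=400), feature_names=feats)
        pred = model.predict(X)
        assert pred.shape == y.shape
        assert compute_metrics(y, pred).r2 > 0.5  # loose sanity: original-units round trip works

    def test_json_serialization_is_bit_exact(self, tmp_path, rr_xy):
        X, y, feats = rr_xy
        model = fit_surrogate(X, y, 3, TrainConfig(seed=0, max_epochs=200), feature_names=feats)
        p = tmp_path / "model.json"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(model.W1, back.W1)
        np.testing.assert_array_equal(model.w2, back.w2)
        assert model.b2 == back.b2
        assert back.y_transform.lmbda == model.y_transform.lmbda
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
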