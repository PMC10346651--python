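"""Hourglass regressor: architecture, splitting, training, prediction."""

import warnings

import numpy as np
import pytest

import spinesense as ss
from spinesense import curvenet


class TestBuildModel:
    def test_default_architecture_parameter_count(self):
        # closed form: sum of w_i*w_{i+1} + w_{i+1} over consecutive widths
        widths = (9, 27, 18, 9, 18, 27)
        expected = sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
        net = curvenet.build_model(ss.ModelConfig())
        assert net.widths == widths
        assert net.n_parameters == expected == 1638

    def test_same_seed_gives_identical_weights(self):
        a = curvenet.build_model(ss.ModelConfig(init_seed=4))
        b = curvenet.build_model(ss.ModelConfig(init_seed=4))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_wrong_input_or_output_width_rejected(self):
        with pytest.raises(ValueError):
            ss.ModelConfig(layer_widths=(8, 27, 18, 9, 18, 27))
        with pytest.raises(ValueError):
            ss.ModelConfig(layer_widths=(9, 27, 18, 9, 18, 26))

    def test_forward_matches_independent_sklearn_evaluation(self):
        """Dual-route check: our forward pass vs sklearn's MLPRegressor
        evaluating the very same weights."""
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPRegressor

        net = curvenet.build_model(ss.ModelConfig(init_seed=12))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(64, 9))
        ref = MLPRegressor(
            hidden_layer_sizes=(27, 18, 9, 18), activation="relu", max_iter=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ref.fit(x, rng.normal(size=(64, 27)))
        ref.coefs_ = [w.copy() for w in net.weights]
        ref.intercepts_ = [b.copy() for b in net.biases]
        np.testing.assert_allclose(net.forward(x), ref.predict(x), atol=1e-6)


class TestSplitSessions:
    def test_four_equal_sessions_split_2_1_1(self):
        sizes = {f"s{i}": 100 for i in range(4)}
        split = curvenet.split_sessions(sizes, ss.SplitSpec(split_seed=0))
        counts = {p: sum(1 for v in split.values() if v == p) for p in ("train", "validation", "test")}
        assert counts == {"train": 2, "validation": 1, "test": 1}

    def test_no_session_in_two_parts_and_deterministic(self):
        rng = np.random.default_rng(1)
        sizes = {f"s{i}": int(rng.integers(500, 5000)) for i in range(15)}
        a = curvenet.split_sessions(sizes, ss.SplitSpec(split_seed=9))
        b = curvenet.split_sessions(sizes, ss.SplitSpec(split_seed=9))
        assert a == b
        assert set(a) == set(sizes)

    def test_frame_fractions_near_targets_on_realistic_sessions(self):
        rng = np.random.default_rng(2)
        sizes = {f"s{i}": int(rng.integers(2000, 7000)) for i in range(15)}
        split = curvenet.split_sessions(sizes, ss.SplitSpec(split_seed=3))
        total = sum(sizes.values())
        for part, target in zip(("train", "validation", "test"), (0.5, 0.25, 0.25)):
            frac = sum(sizes[s] for s, p in split.items() if p == part) / total
            assert abs(frac - target) < 0.10

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="3 sessions"):
            curvenet.split_sessions({"a": 10, "b": 10})

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            ss.SplitSpec(proportions=(0.5, 0.3, 0.3))


class TestTrainingPairs:
    def test_marker_one_never_in_targets(self):
        rng = np.random.default_rng(0)
        curves = rng.normal(size=(50, 10, 3))
        curves[:, 0, :] = 0.0
        imu = rng.normal(size=(50, 9))
        x, y = curvenet.make_training_pairs(imu, curves)
        assert x.shape == (50, 9) and y.shape == (50, 27)
        np.testing.assert_array_equal(y, curves[:, 1:, :].reshape(50, 27))

    def test_unsynchronized_streams_rejected(self):
        with pytest.raises(ValueError, match="synchronize"):
            curvenet.make_training_pairs(np.zeros((5, 9)), np.zeros((6, 10, 3)))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="9 IMU channels"):
            curvenet.make_training_pairs(np.zeros((5, 8)), np.zeros((5, 10, 3)))


class TestTrain:
    def test_constant_target_reaches_variance_floor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(512, 9))
        y = np.full((512, 27), 0.25)
        net = curvenet.build_model(ss.ModelConfig(init_seed=0))
        cfg = ss.TrainingConfig(learning_rate=1e-2, epochs=200, batch_size=128, shuffle_seed=0)
        m = curvenet.train(net, x, y, config=cfg)
        assert m.history["train_loss"][-1] < 1e-3

    def test_identical_seeds_reproduce_final_losses(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(600, 9))
        y = rng.normal(size=(600, 27)) * 0.1
        cfg = ss.TrainingConfig(epochs=5, shuffle_seed=2)
        runs = []
        for _ in range(2):
            net = curvenet.build_model(ss.ModelConfig(init_seed=2))
            m = curvenet.train(net, x, y, config=cfg)
            runs.append(m.history["train_loss"][-1])
        assert runs[0] == runs[1]

    def test_final_loss_not_above_initial(self, experiment):
        h = experiment.model.history["train_loss"]
        assert h[-1] <= h[0]
        assert len(h) == 250

    def test_validation_mse_improves_tenfold(self, experiment):
        v = experiment.model.history["val_loss"]
        assert v[-1] * 10 < v[0]

    def test_smoothed_training_loss_non_increasing(self, experiment):
        h = np.array(experiment.model.history["train_loss"])
        ma = np.convolve(h, np.ones(10) / 10, mode="valid")
        # slack of 2% absorbs mini-batch shot noise around the plateau
        assert np.all(ma[1:] <= ma[:-1] * 1.02)

    def test_empty_training_set_rejected(self):
        net = curvenet.build_model(ss.ModelConfig())
        with pytest.raises(ValueError, match="empty"):
            curvenet.train(net, np.zeros((0, 9)), np.zeros((0, 27)))

    def test_diverging_loss_aborts_with_diagnostic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(256, 9)) * 1e3
        y = rng.normal(size=(256, 27)) * 1e3
        net = curvenet.build_model(ss.ModelConfig(init_seed=0))
        for w in net.weights:
            w *= 1e150  # force overflow in the first forward pass
        with pytest.raises(FloatingPointError, match="non-finite"):
            with np.errstate(over="ignore", invalid="ignore"):
                curvenet.train(net, x, y, config=ss.TrainingConfig(epochs=1))


class TestPredictCurve:
    def test_zero_weight_model_puts_all_markers_at_origin(self, trained_toy_model):
        m = trained_toy_model
        for w in m.net.weights:
            w[:] = 0.0
        for b in m.net.biases:
            b[:] = 0.0
        curve = curvenet.predict_curve(m, np.ones(9))
        np.testing.assert_array_equal(curve, np.zeros((10, 3)))

    def test_structural_contract_ten_points_origin_first(self, trained_toy_model):
        curve = curvenet.predict_curve(trained_toy_model, np.ones(9))
        assert curve.shape == (10, 3)
        np.testing.assert_array_equal(curve[0], np.zeros(3))

    def test_prediction_is_pure_function(self, trained_toy_model):
        x = np.linspace(-1, 1, 9)
        a = curvenet.predict_curve(trained_toy_model, x)
        b = curvenet.predict_curve(trained_toy_model, x)
        np.testing.assert_array_equal(a, b)

    def test_channel_count_mismatch_rejected(self, trained_toy_model):
        with pytest.raises(ValueError, match="9 IMU channels"):
            curvenet.predict_curve(trained_toy_model, np.ones(8))

    def test_denormalization_uses_stored_spec(self, trained_toy_model):
        m = trained_toy_model
        for w in m.net.weights:
            w[:] = 0.0
        for b in m.net.biases:
            b[:] = 0.0
        m.net.biases[-1][:] = 1.0  # normalized units
        curve = curvenet.predict_curve(m, np.zeros(9))
        np.testing.assert_allclose(curve[1:], np.tile([50.0, 500.0, 50.0], (9, 1)))


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, trained_toy_model):
        p = tmp_path / "model.npz"
        curvenet.save_model(trained_toy_model, p)
        loaded = curvenet.load_model(p)
        x = np.linspace(-1, 1, 9)
        np.testing.assert_array_equal(
            curvenet.predict_curve(trained_toy_model, x), curvenet.predict_curve(loaded, x)
        )
        assert loaded.norm_spec == trained_toy_model.norm_spec
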