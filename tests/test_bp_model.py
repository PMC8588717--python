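import numpy as np
import pytest

from ferrospec.bp_model import (
    BPConfig,
    evaluate,
    load_model,
    predict,
    save_model,
    split_dataset,
    train_bp,
)
from ferrospec.spectra_io import SpectralDataset
from ferrospec.synthetic_data import default_profiles, generate


def make_dataset(n, soil):
    rng = np.random.default_rng(n)
    wl = np.array([400.0, 500.0, 600.0])
    return SpectralDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        wavelengths=wl,
        spectra=rng.uniform(0.2, 0.8, size=(n, 3)),
        tics=rng.uniform(10, 30, n),
        soil_type=np.array([soil] * n, dtype=object),
    )


class TestSplit:
    def test_loessial_51_splits_35_16(self):
        ds = make_dataset(51, "loessial")
        train, test = split_dataset(ds, scheme="per-soil", seed=3)
        assert train.size == 35 and test.size == 16
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == 51

    def test_sandy_33_splits_20_13(self):
        ds = make_dataset(33, "sandy")
        train, test = split_dataset(ds, scheme="per-soil", seed=3)
        assert train.size == 20 and test.size == 13

    def test_pooled_84_splits_45_39(self):
        ds = generate(default_profiles(seed=0)["mixed"])
        train, test = split_dataset(ds, scheme="pooled", seed=1)
        assert train.size == 45 and test.size == 39

    def test_same_seed_reproduces_split(self):
        ds = make_dataset(51, "loessial")
        a = split_dataset(ds, scheme="per-soil", seed=9)
        b = split_dataset(ds, scheme="per-soil", seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_off_count_falls_back_to_proportional(self):
        ds = make_dataset(40, "loessial")  # expected 51
        with pytest.warns(UserWarning, match="proportional"):
            train, test = split_dataset(ds, scheme="per-soil", seed=0)
        assert train.size == round(40 * 35 / 51)
        assert train.size + test.size == 40


class TestTraining:
    def test_constant_target_fit(self, rng):
        x = rng.uniform(-1, 1, size=(20, 2))
        y = np.full(20, 21.0)
        model = train_bp(x, y, BPConfig(topology=(2, 3, 1), seed=0))
        np.testing.assert_allclose(predict(model, x), 21.0, atol=0.21)

    def test_linear_toy_converges_below_goal(self, rng):
        x = rng.uniform(-1, 1, size=(30, 1))
        y = 2.0 * x[:, 0]
        model = train_bp(x, y, BPConfig(topology=(1, 3, 1), seed=1))
        assert model.loss_trace[-1] <= model.config.goal_mse
        assert len(model.loss_trace) <= 2000

    def test_same_seed_bitwise_identical_trace(self, rng):
        x = rng.uniform(-1, 1, size=(25, 5))
        y = x @ rng.normal(size=5) + 20.0
        a = train_bp(x, y, BPConfig(seed=7))
        b = train_bp(x, y, BPConfig(seed=7))
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)

    def test_wrong_width_rejected(self, rng):
        x = rng.uniform(-1, 1, size=(15, 3))
        with pytest.raises(ValueError, match="topology"):
            train_bp(x, np.ones(15) * 20, BPConfig(topology=(5, 3, 1)))

    def test_divergence_reports_iteration(self, rng):
        x = rng.uniform(-1, 1, size=(20, 2))
        y = rng.uniform(10, 30, 20)
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train_bp(x, y, BPConfig(topology=(2, 3, 1), learning_rate=50.0, seed=0))


class TestPredict:
    def test_referential_transparency_on_training_inputs(self, rng):
        x = rng.uniform(-1, 1, size=(20, 5))
        y = x @ rng.normal(size=5) + 20.0
        model = train_bp(x, y, BPConfig(seed=2))
        np.testing.assert_allclose(predict(model, x), predict(model, x), rtol=1e-15)

    def test_zero_weight_model_outputs_inverse_scaled_bias(self, rng):
        x = rng.uniform(-1, 1, size=(12, 5))
        y = rng.uniform(10, 30, 12)
        model = train_bp(x, y, BPConfig(seed=3, max_iterations=1))
        model.w_out[:] = 0.0
        model.b_out = 0.5
        expected = (0.5 + 1.0) / 2.0 * (model.y_max - model.y_min) + model.y_min
        np.testing.assert_allclose(predict(model, x), expected)

    def test_manual_forward_pass_toy(self, rng):
        """Hand-computed 2-2-1 forward pass with pinned weights."""
        x = rng.uniform(-1, 1, size=(12, 2))
        y = rng.uniform(10, 30, 12)
        model = train_bp(x, y, BPConfig(topology=(2, 2, 1), seed=4, max_iterations=1))
        model.w_hidden = np.array([[0.1, -0.2], [0.3, 0.4]])
        model.b_hidden = np.array([0.05, -0.05])
        model.w_out = np.array([0.7, -0.6])
        model.b_out = 0.1
        probe = np.array([[0.2, 0.5]])
        xs = 2.0 * (probe - model.x_min) / (model.x_max - model.x_min) - 1.0
        h1 = np.tanh(0.1 * xs[0, 0] - 0.2 * xs[0, 1] + 0.05)
        h2 = np.tanh(0.3 * xs[0, 0] + 0.4 * xs[0, 1] - 0.05)
        ys = 0.7 * h1 - 0.6 * h2 + 0.1
        expected = (ys + 1.0) / 2.0 * (model.y_max - model.y_min) + model.y_min
        assert predict(model, probe)[0] == pytest.approx(expected, rel=1e-12)

    def test_width_mismatch_rejected(self, rng):
        x = rng.uniform(-1, 1, size=(15, 5))
        y = rng.uniform(10, 30, 15)
        model = train_bp(x, y, BPConfig(seed=5, max_iterations=1))
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 4)))


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.rmse == 0.0 and rep.mae == 0.0 and rep.r_squared == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        rep = evaluate([1.0, 3.0], [2.0, 4.0])
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        y = rng.uniform(10, 30, 20)
        yhat = y + rng.normal(0, 2, 20)
        rep = evaluate(y, yhat)
        rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 20)
        mae = sum(abs(a - b) for a, b in zip(y, yhat)) / 20
        assert rep.rmse == pytest.approx(rmse, rel=1e-12)
        assert rep.mae == pytest.approx(mae, rel=1e-12)
        assert rep.r_squared == pytest.approx(np.corrcoef(y, yhat)[0, 1] ** 2, rel=1e-12)

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(50):
            y = rng.normal(size=10)
            yhat = rng.normal(size=10)
            rep = evaluate(y, yhat)
            assert rep.mae <= rep.rmse + 1e-12

    def test_translation_invariance(self, rng):
        y = rng.uniform(10, 30, 15)
        yhat = y + rng.normal(0, 1, 15)
        a = evaluate(y, yhat)
        b = evaluate(y + 100.0, yhat + 100.0)
        assert a.rmse == pytest.approx(b.rmse)
        assert a.mae == pytest.approx(b.mae)

    def test_zero_variance_flagged(self):
        rep = evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert rep.r2_undefined and rep.r_squared == 0.0

    def test_sse_mode(self, rng):
        y = rng.uniform(10, 30, 20)
        yhat = y + rng.normal(0, 1, 20)
        rep = evaluate(y, yhat, r2_mode="sse")
        expected = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert rep.r_squared == pytest.approx(expected, rel=1e-12)


def test_model_roundtrip_serialization(tmp_path, rng):
    x = rng.uniform(-1, 1, size=(20, 5))
    y = x @ rng.normal(size=5) + 20.0
    model = train_bp(x, y, BPConfig(seed=11))
    save_model(model, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    np.testing.assert_allclose(predict(back, x), predict(model, x), rtol=1e-12)
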