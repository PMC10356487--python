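import numpy as np
import pytest

import kicksense as ks
from kicksense.exceptions import ConfigurationError
from kicksense.network import LSTMNetwork


def loop_cross_entropy(probs, labels, eps=1e-12):
    N, C = probs.shape
    total = 0.0
    for i in range(N):
        for c in range(C):
            if labels[i] == c:
                total += np.log(max(probs[i, c], eps))
    return -total / N


def loop_mse(pred, target):
    return sum((t - p) ** 2 for p, t in zip(pred, target)) / len(pred)


def random_simplex_batch(rng, n, c):
    p = rng.random((n, c))
    return p / p.sum(axis=1, keepdims=True)


class TestLosses:
    def test_perfect_onehot_has_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert ks.classification_loss(probs, [0, 1, 2]) == pytest.approx(0.0)

    @pytest.mark.parametrize("C", [2, 3, 5])
    def test_uniform_predictions_give_log_C(self, C):
        probs = np.full((4, C), 1.0 / C)
        assert ks.classification_loss(probs, [0] * 4) == pytest.approx(np.log(C))

    def test_cross_entropy_matches_loop_oracle(self, rng):
        probs = random_simplex_batch(rng, 5, 3)
        labels = rng.integers(0, 3, size=5)
        assert ks.classification_loss(probs, labels) == pytest.approx(
            loop_cross_entropy(probs, labels), abs=1e-9
        )

    def test_zero_probability_is_clamped_finite(self):
        probs = np.array([[0.0, 1.0]])
        assert np.isfinite(ks.classification_loss(probs, [0]))

    def test_mse_identical_is_zero(self):
        assert ks.regression_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mse_example(self):
        assert ks.regression_loss([0.0, 0.0], [1.0, 3.0]) == pytest.approx(5.0)

    def test_mse_matches_loop_oracle(self, rng):
        p, t = rng.normal(size=8), rng.normal(size=8)
        assert ks.regression_loss(p, t) == pytest.approx(loop_mse(p, t), abs=1e-12)

    def test_mse_is_nonnegative(self, rng):
        for _ in range(10):
            assert ks.regression_loss(rng.normal(size=4), rng.normal(size=4)) >= 0

    def test_composite_weighting_example(self):
        cfg = ks.MultitaskModelConfig(alpha_c=1.0, alpha_i=0.001)
        # the stated starting magnitudes: Lc about 3.5, Li about 6000
        assert ks.composite_loss(3.5, 6000.0, cfg) == pytest.approx(9.5)

    def test_composite_degenerates_to_each_head(self):
        only_c = ks.MultitaskModelConfig(alpha_c=1.0, alpha_i=0.0)
        only_i = ks.MultitaskModelConfig(alpha_c=0.0, alpha_i=1.0)
        assert ks.composite_loss(2.5, 7.0, only_c) == 2.5
        assert ks.composite_loss(2.5, 7.0, only_i) == 7.0

    def test_composite_linear_in_each_weight(self):
        lc, li = 1.7, 42.0
        vals = [
            ks.composite_loss(lc, li, ks.MultitaskModelConfig(alpha_c=a, alpha_i=0.5))
            for a in (0.0, 1.0, 2.0)
        ]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0])


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        m, H, C, F = 4, 32, 2, 32
        cfg = ks.MultitaskModelConfig(hidden_units=H, num_classes=C,
                                      extra_fc_units=F)
        net = ks.build_model(cfg, input_shape=(16, m))
        expected = (
            4 * H * (m + H + 1)      # LSTM gates
            + H * C + C              # softmax head
            + H * F + F              # regression FC
            + F * 1 + 1              # regression output
        )
        assert net.n_params == expected

    def test_two_layer_encoder_feeds_layer_two(self, rng):
        cfg = ks.MultitaskModelConfig(lstm_layers=2, hidden_units=8,
                                      dropout_rate=0.0)
        net = ks.build_model(cfg, input_shape=(6, 4))
        cache = net.forward(rng.normal(size=(3, 6, 4)))
        # layer 2 consumes layer 1's full hidden sequence
        assert cache["layers"][1]["input"].shape == (3, 6, 8)
        assert cache["encoded"].shape == (3, 6, 8)

    def test_same_seed_gives_bit_identical_weights(self):
        cfg = ks.MultitaskModelConfig(seed=11)
        a = ks.build_model(cfg, (16, 4))
        b = ks.build_model(cfg, (16, 4))
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ks.MultitaskModelConfig(dropout_rate=1.0)
        with pytest.raises(ConfigurationError):
            ks.MultitaskModelConfig(lstm_layers=3)
        with pytest.raises(ConfigurationError):
            ks.MultitaskModelConfig(alpha_c=-1.0)


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        """Backprop through the full network vs central differences."""
        cfg = ks.MultitaskModelConfig(
            lstm_layers=2, hidden_units=3, extra_fc_units=2, num_classes=3,
            dropout_rate=0.0, reg_constant=2e-4, alpha_c=1.0, alpha_i=0.5,
            seed=5,
        )
        rng = np.random.default_rng(0)
        net = LSTMNetwork(cfg, input_dim=2, rng=rng)
        X = rng.normal(size=(3, 4, 2))
        yc = np.array([0, 2, 1])
        yi = np.array([1.0, 3.0, 0.5])
        grads = net.backward(net.forward(X), yc, yi)

        def total_loss():
            return net.loss(net.forward(X), yc, yi)["loss"]

        eps = 1e-6
        for name, p in net.params.items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + eps
                lp = total_loss()
                p[ix] = orig - eps
                lm = total_loss()
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, abs=1e-4, rel=1e-4)


def separable_sequences(rng, n=60, T=6, m=3):
    y = rng.integers(0, 2, size=n)
    X = rng.normal(0, 0.2, size=(n, T, m)) + (2.0 * y - 1.0)[:, None, None]
    yi = 1.0 + 3.0 * y
    return X, y, yi


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self, rng):
        X, y, yi = separable_sequences(rng)
        cfg = ks.MultitaskModelConfig(hidden_units=8, extra_fc_units=8,
                                      batch_size=32, seed=2)
        res = ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=500)
        probs, _ = res.predict_arrays(X)
        assert (probs.argmax(1) == y).mean() >= 0.95

    def test_same_seed_and_data_reproduce_final_loss(self, rng):
        X, y, yi = separable_sequences(rng, n=30)
        cfg = ks.MultitaskModelConfig(hidden_units=4, batch_size=16, seed=9)
        a = ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=50)
        b = ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=50)
        assert a.final_loss == b.final_loss
        for name in a.network.params:
            np.testing.assert_array_equal(
                a.network.params[name], b.network.params[name]
            )

    def test_zero_intensity_weight_freezes_regression_head(self, rng):
        X, y, yi = separable_sequences(rng, n=30)
        cfg = ks.MultitaskModelConfig(hidden_units=4, batch_size=16, seed=9,
                                      alpha_i=0.0)
        fresh = LSTMNetwork(cfg, input_dim=3,
                            rng=np.random.default_rng(cfg.seed))
        res = ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=40)
        for name in ("Wf", "bf", "Wr", "br"):
            np.testing.assert_array_equal(res.network.params[name],
                                          fresh.params[name])
        # ... while the classification path did move
        assert not np.array_equal(res.network.params["Wc"], fresh.params["Wc"])

    def test_nonfinite_loss_aborts_with_diagnostic(self, rng):
        X, y, _ = separable_sequences(rng, n=20)
        yi = np.full(20, np.inf)
        cfg = ks.MultitaskModelConfig(hidden_units=4, batch_size=8, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=5)

    def test_training_log_records_every_iteration(self, rng):
        X, y, yi = separable_sequences(rng, n=20)
        cfg = ks.MultitaskModelConfig(hidden_units=4, batch_size=8, seed=0)
        res = ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=25)
        assert list(res.training_log.columns) == ["iteration", "lc", "li", "loss"]
        assert len(res.training_log) == 25


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    X, y, yi = separable_sequences(rng, n=40)
    cfg = ks.MultitaskModelConfig(hidden_units=6, batch_size=16, seed=3)
    return ks.MultitaskLSTM(X, y, yi, config=cfg).fit(iterations=150), X


class TestPrediction:

    def test_probabilities_sum_to_one(self, fitted, rng):
        res, _ = fitted
        preds = res.predict(rng.normal(size=(5, 6, 3)))
        for p in preds:
            assert p.class_probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_count_mode_intensity_is_nonnegative_integer(self, fitted, rng):
        res, _ = fitted
        for p in res.predict(rng.normal(size=(5, 6, 3))):
            assert p.intensity >= 0
            assert p.intensity == int(p.intensity)

    def test_inference_is_deterministic(self, fitted, rng):
        res, _ = fitted
        x = rng.normal(size=(2, 6, 3))
        a, b = res.predict(x), res.predict(x)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.class_probs, pb.class_probs)
            assert pa.intensity_raw == pb.intensity_raw

    def test_both_heads_share_the_encoder_state(self, fitted):
        """One forward pass serves both heads from the same hidden state."""
        res, X = fitted
        net = res.network
        Xn = res.model._normalize(X[:4])
        cache = net.forward(Xn)
        from kicksense.network import softmax

        probs = softmax(cache["h_last"] @ net.params["Wc"] + net.params["bc"])
        a = np.maximum(cache["h_last"] @ net.params["Wf"] + net.params["bf"], 0)
        yhat = (a @ net.params["Wr"]).ravel() + net.params["br"][0]
        np.testing.assert_allclose(cache["probs"], probs, atol=1e-12)
        np.testing.assert_allclose(cache["intensity"], yhat, atol=1e-12)

    def test_save_load_round_trip(self, fitted, tmp_path, rng):
        res, _ = fitted
        res.save(tmp_path / "m")
        back = ks.MultitaskLSTMResults.load(tmp_path / "m")
        x = rng.normal(size=(3, 6, 3))
        pa, pb = res.predict(x), back.predict(x)
        for a, b in zip(pa, pb):
            np.testing.assert_allclose(a.class_probs, b.class_probs, atol=1e-12)
            assert a.intensity_raw == pytest.approx(b.intensity_raw, abs=1e-12)
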