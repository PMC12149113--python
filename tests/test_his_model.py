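"""Model mathematics: gate recurrence, attention, loss, and backprop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hisforecast import (
    ModelConfig,
    apply_dropconnect,
    attention_weights,
    composite_loss,
    composite_loss_segmented,
    context_vector,
    forward_backward,
    init_params,
    load_checkpoint,
    lstm_stack_forward,
    output_head,
    predict,
    save_checkpoint,
)
from hisforecast.his_model import (
    LayerParams,
    ModelParams,
    flatten_params,
    unflatten_params,
)


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def scalar_model(w_x, w_h, b, wa=1.0, w_out=1.0, b_out=0.0):
    """hidden_size=1, n_channels=1, single layer; gate order (i, f, g, o)."""
    return ModelParams(
        layers=[LayerParams(
            W_x=np.array(w_x, dtype=float).reshape(4, 1),
            W_h=np.array(w_h, dtype=float).reshape(4, 1),
            b=np.array(b, dtype=float),
        )],
        W_a=np.array([[wa]], dtype=float),
        W_out=np.array([[w_out]], dtype=float),
        b_out=np.array([b_out], dtype=float),
    )


def scalar_config(T=2, **kw):
    defaults = dict(n_channels=1, n_layers=1, hidden_size=1, window=T, horizon=1,
                    dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def hand_lstm_step(x, h_prev, c_prev, w_x, w_h, b):
    """Independent scalar trace of the gate equations."""
    i = sigmoid(w_x[0] * x + w_h[0] * h_prev + b[0])
    f = sigmoid(w_x[1] * x + w_h[1] * h_prev + b[1])
    g = math.tanh(w_x[2] * x + w_h[2] * h_prev + b[2])
    o = sigmoid(w_x[3] * x + w_h[3] * h_prev + b[3])
    c = f * c_prev + i * g
    h = o * math.tanh(c)
    return h, c


class TestLstmStack:
    def test_zero_input_zero_weights_gives_zero_states(self):
        params = scalar_model([0] * 4, [0] * 4, [0] * 4)
        state = lstm_stack_forward(np.zeros((2, 1)), params, scalar_config())
        np.testing.assert_array_equal(state.h, 0.0)
        np.testing.assert_array_equal(state.c, 0.0)

    def test_matches_hand_executed_gate_trace(self):
        w_x, w_h, b = [0.5, -0.3, 0.8, 0.2], [0.1, 0.4, -0.2, 0.3], [0.05, 1.0, -0.1, 0.2]
        params = scalar_model(w_x, w_h, b)
        x = [0.7, -0.4]
        h1, c1 = hand_lstm_step(x[0], 0.0, 0.0, w_x, w_h, b)
        h2, c2 = hand_lstm_step(x[1], h1, c1, w_x, w_h, b)
        state = lstm_stack_forward(np.array(x).reshape(2, 1), params, scalar_config())
        np.testing.assert_allclose(state.top[:, 0], [h1, h2], atol=1e-10)
        np.testing.assert_allclose(state.c[0, :, 0], [c1, c2], atol=1e-10)

    def test_eval_mode_deterministic(self, tiny_model):
        cfg, params = tiny_model
        x = np.random.default_rng(0).random((7, 20))
        a = lstm_stack_forward(x, params, cfg)
        b = lstm_stack_forward(x, params, cfg)
        np.testing.assert_array_equal(a.h, b.h)

    def test_shape_mismatch_rejected(self, tiny_model):
        cfg, params = tiny_model
        with pytest.raises(ValueError, match="shape"):
            lstm_stack_forward(np.zeros((7, 3)), params, cfg)

    def test_stacked_layers_consume_lower_output(self):
        cfg = scalar_config(n_layers=2)
        params = init_params(cfg, seed=1)
        state = lstm_stack_forward(np.array([[0.3], [0.9]]), params, cfg)
        assert state.h.shape == (2, 2, 1)
        assert not np.allclose(state.h[0], state.h[1])


class TestAttention:
    def test_singleton_window(self):
        alpha = attention_weights(np.array([[1.0, 2.0]]), np.eye(2))
        np.testing.assert_allclose(alpha, [1.0])

    def test_zero_matrix_gives_uniform(self):
        H = np.random.default_rng(0).random((5, 3))
        np.testing.assert_allclose(attention_weights(H, np.zeros((3, 3))), np.full(5, 0.2))

    def test_hand_softmax_example(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        alpha = attention_weights(H, np.eye(2))  # logits (0, 1)
        np.testing.assert_allclose(alpha, [0.2689, 0.7311], atol=1e-4)

    def test_overflow_safe(self):
        H = np.array([[1000.0], [999.0]])
        alpha = attention_weights(H, np.array([[1000.0]]))
        assert np.isfinite(alpha).all() and alpha.sum() == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            attention_weights(np.array([[np.nan]]), np.eye(1))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_simplex_property(self, seed):
        rng = np.random.default_rng(seed)
        T, Hd = rng.integers(1, 9), rng.integers(1, 6)
        alpha = attention_weights(rng.normal(size=(T, Hd)) * 3,
                                  rng.normal(size=(Hd, Hd)))
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(alpha >= 0)


class TestContextAndHead:
    def test_one_hot_selects_state(self):
        H = np.random.default_rng(0).random((4, 3))
        alpha = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(context_vector(H, alpha), H[2])

    def test_uniform_is_mean(self):
        H = np.random.default_rng(1).random((4, 3))
        np.testing.assert_allclose(context_vector(H, np.full(4, 0.25)), H.mean(axis=0))

    def test_weighted_sum_example(self):
        np.testing.assert_allclose(
            context_vector(np.array([[4.0], [8.0]]), np.array([0.25, 0.75])), [7.0]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            context_vector(np.zeros((3, 2)), np.array([0.5, 0.5]))

    def test_head_examples(self):
        np.testing.assert_allclose(output_head(np.zeros(3), np.zeros((1, 3)), np.zeros(1)), [0.0])
        np.testing.assert_allclose(
            output_head(np.array([1.0, 2.0]), np.array([[1.0, 1.0]]), np.array([0.5])), [3.5]
        )
        np.testing.assert_allclose(
            output_head(np.zeros(2), np.zeros((1, 2)), np.zeros(1), "scaled_sigmoid"), [0.5]
        )


class TestCompositeLoss:
    def test_lambda_zero_is_plain_mse(self):
        rng = np.random.default_rng(0)
        y, p = rng.random((4, 3)), rng.random((4, 3))
        assert composite_loss(y, p, 0.0) == pytest.approx(np.mean((y - p) ** 2))

    def test_constant_predictions_zero_smoothness(self):
        y = np.array([[1.0, 2.0, 3.0]])
        p = np.full((1, 3), 2.0)
        assert composite_loss(y, p, 5.0) == pytest.approx(np.mean((y - p) ** 2))

    def test_worked_example(self):
        loss = composite_loss(np.array([1.0, 2.0]), np.array([1.5, 2.5]), 0.1)
        assert loss == pytest.approx(0.35, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0])
    def test_decomposes_linearly_in_lambda(self, lam):
        rng = np.random.default_rng(3)
        y, p = rng.random((5, 4)), rng.random((5, 4))
        base = composite_loss(y, p, 0.0)
        d = p[:, :-1] - p[:, 1:]
        smooth = np.mean(np.sum(d**2, axis=1) / 3)
        assert composite_loss(y, p, lam) == pytest.approx(base + lam * smooth, rel=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            composite_loss(np.ones(2), np.ones(2), -0.1)

    def test_segmented_matches_manual(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([1.5, 2.5, 2.0, 4.5])
        seg = np.array(["a", "a", "b", "b"])
        mse = np.mean((p - y) ** 2)
        smooth = ((1.5 - 2.5) ** 2 + (2.0 - 4.5) ** 2) / 2  # within-participant pairs
        assert composite_loss_segmented(y, p, 0.2, seg) == pytest.approx(mse + 0.2 * smooth)

    def test_segmented_no_pairs_is_mse(self):
        y, p = np.array([1.0, 2.0]), np.array([0.5, 2.5])
        seg = np.array(["a", "b"])
        assert composite_loss_segmented(y, p, 9.0, seg) == pytest.approx(np.mean((p - y) ** 2))

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(5)
        y, p = rng.random((3, 4)), rng.random((3, 4))
        _, grad = composite_loss(y, p, 0.3, return_grad=True)
        eps = 1e-7
        for idx in np.ndindex(p.shape):
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            num = (composite_loss(y, pp, 0.3) - composite_loss(y, pm, 0.3)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-6)


class TestDropConnect:
    def test_rate_zero_identity_both_modes(self):
        W = np.random.default_rng(0).random((5, 5))
        rng = np.random.default_rng(1)
        np.testing.assert_array_equal(apply_dropconnect(W, 0.0, rng, "train"), W)
        np.testing.assert_array_equal(apply_dropconnect(W, 0.0, None, "eval"), W)

    def test_eval_mode_identity(self):
        W = np.random.default_rng(0).random((5, 5))
        np.testing.assert_array_equal(apply_dropconnect(W, 0.5, None, "eval"), W)

    def test_zero_fraction_within_binomial_bound(self):
        from scipy import stats
        W = np.ones((40, 25))  # 1000 weights
        out = apply_dropconnect(W, 0.5, np.random.default_rng(7), "train")
        zeros = int((out == 0).sum())
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= zeros <= hi
        # survivors rescaled by 1/(1-rate)
        assert np.allclose(out[out != 0], 2.0)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            apply_dropconnect(np.ones((2, 2)), 1.0, None, "eval")


class TestPredict:
    def test_eval_determinism_bitwise(self, tiny_model):
        cfg, params = tiny_model
        X = np.random.default_rng(2).random((4, 7, 20))
        a, b = predict(X, params, cfg), predict(X, params, cfg)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.attention.alpha, b.attention.alpha)

    def test_attention_simplex(self, tiny_model):
        cfg, params = tiny_model
        X = np.random.default_rng(3).random((8, 7, 20))
        alpha = predict(X, params, cfg).attention.alpha
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(alpha >= 0)

    def test_end_to_end_scalar_oracle(self):
        """Hand-chain recurrence -> attention -> context -> head at scalar size."""
        w_x, w_h, b = [0.5, -0.3, 0.8, 0.2], [0.1, 0.4, -0.2, 0.3], [0.05, 1.0, -0.1, 0.2]
        wa, w_out, b_out = 1.7, 2.0, 0.25
        params = scalar_model(w_x, w_h, b, wa=wa, w_out=w_out, b_out=b_out)
        x = [0.7, -0.4]
        h1, c1 = hand_lstm_step(x[0], 0.0, 0.0, w_x, w_h, b)
        h2, _ = hand_lstm_step(x[1], h1, c1, w_x, w_h, b)
        e1, e2 = h1 * wa * h2, h2 * wa * h2
        a1 = math.exp(e1) / (math.exp(e1) + math.exp(e2))
        ctx = a1 * h1 + (1 - a1) * h2
        expected = w_out * ctx + b_out
        pred = predict(np.array(x).reshape(2, 1), params, scalar_config())
        assert pred.y[0] == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(pred.attention.alpha, [a1, 1 - a1], atol=1e-10)

    def test_plain_pooling_returns_last_state(self):
        cfg = scalar_config(attention=False)
        params = scalar_model([0.5, -0.3, 0.8, 0.2], [0.1, 0.4, -0.2, 0.3],
                              [0.05, 1.0, -0.1, 0.2], w_out=1.0, b_out=0.0)
        state = lstm_stack_forward(np.array([[0.7], [-0.4]]), params, cfg)
        pred = predict(np.array([[0.7], [-0.4]]), params, cfg)
        assert pred.y[0] == pytest.approx(state.top[-1, 0], abs=1e-12)


def _numeric_grad(X, y, params, cfg, mode, seed, step=1e-6):
    theta = flatten_params(params)
    num = np.zeros_like(theta)
    for i in range(theta.size):
        outs = []
        for delta in (step, -step):
            tp = theta.copy(); tp[i] += delta
            rng = np.random.default_rng(seed)  # identical masks per evaluation
            loss, _ = forward_backward(X, y, unflatten_params(tp, params), cfg,
                                       mode=mode, rng=rng)
            outs.append(loss)
        num[i] = (outs[0] - outs[1]) / (2 * step)
    return num


class TestGradients:
    def test_analytic_matches_finite_difference_eval(self):
        cfg = ModelConfig(n_channels=2, n_layers=1, hidden_size=3, window=4, horizon=2,
                          dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.1)
        params = init_params(cfg, seed=1)
        rng = np.random.default_rng(0)
        X, y = rng.random((3, 4, 2)), rng.random((3, 2))
        _, grads = forward_backward(X, y, params, cfg, mode="eval")
        num = _numeric_grad(X, y, params, cfg, "eval", seed=0)
        g = flatten_params(grads)
        rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-4

    def test_analytic_matches_finite_difference_with_dropout_masks(self):
        """Backprop respects the sampled DropConnect/Dropout masks: replaying
        the same rng per evaluation makes finite differences valid."""
        cfg = ModelConfig(n_channels=2, n_layers=2, hidden_size=3, window=3, horizon=1,
                          dropout_rate=0.3, dropconnect_rate=0.3, smoothness_weight=0.0)
        params = init_params(cfg, seed=2)
        data_rng = np.random.default_rng(1)
        X, y = data_rng.random((2, 3, 2)), data_rng.random((2, 1))
        _, grads = forward_backward(X, y, params, cfg, mode="train",
                                    rng=np.random.default_rng(11))
        # wider step: some masked gradients are ~1e-8 and a 1e-6 step is
        # cancellation-limited there
        num = _numeric_grad(X, y, params, cfg, "train", seed=11, step=1e-5)
        g = flatten_params(grads)
        rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-4

    def test_segmented_loss_gradient_through_model(self):
        cfg = ModelConfig(n_channels=2, n_layers=1, hidden_size=2, window=3, horizon=1,
                          dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.5)
        params = init_params(cfg, seed=3)
        rng = np.random.default_rng(2)
        X, y = rng.random((4, 3, 2)), rng.random((4, 1))
        seg = np.array(["a", "a", "a", "b"])
        _, grads = forward_backward(X, y, params, cfg, mode="eval", segments=seg)
        theta = flatten_params(params)
        num = np.zeros_like(theta)
        for i in range(theta.size):
            vals = []
            for d in (1e-6, -1e-6):
                tp = theta.copy(); tp[i] += d
                loss, _ = forward_backward(X, y, unflatten_params(tp, params), cfg,
                                           mode="eval", segments=seg)
                vals.append(loss)
            num[i] = (vals[0] - vals[1]) / 2e-6
        g = flatten_params(grads)
        rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-4


class TestCheckpoint:
    def test_roundtrip_bit_identical_predictions(self, tmp_path, tiny_model):
        cfg, params = tiny_model
        X = np.random.default_rng(4).random((3, 7, 20))
        before = predict(X, params, cfg).y
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg, scalers={"ch0": (0.0, 1.0)}, seed=5)
        params2, cfg2, scalers, seed = load_checkpoint(path)
        assert cfg2 == cfg and seed == 5 and scalers == {"ch0": (0.0, 1.0)}
        np.testing.assert_array_equal(predict(X, params2, cfg2).y, before)
        assert path.with_suffix(".json").exists()
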