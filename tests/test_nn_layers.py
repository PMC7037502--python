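"""Layer-level checks against independent nested-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specnet.nn import (
    Conv1d,
    Conv2d,
    Dense,
    Dropout,
    Network,
    Pool1d,
    Pool2d,
    ReLU,
    relu,
    softmax,
)


def conv1d_oracle(x, W, b):
    """Triple-loop valid cross-correlation, one input sample."""
    n_k, n_c, m = W.shape
    out_len = x.shape[-1] - m + 1
    out = np.zeros((n_k, out_len))
    for i in range(n_k):
        for t in range(out_len):
            s = 0.0
            for c in range(n_c):
                for k in range(m):
                    s += x[c, t + k] * W[i, c, k]
            out[i, t] = s + b[i]
    return out


def conv2d_oracle(x, W, b):
    n_k, n_c, kh, kw = W.shape
    H = x.shape[1] - kh + 1
    Wd = x.shape[2] - kw + 1
    out = np.zeros((n_k, H, Wd))
    for i in range(n_k):
        for r in range(H):
            for col in range(Wd):
                s = 0.0
                for c in range(n_c):
                    for a in range(kh):
                        for bb in range(kw):
                            s += x[c, r + a, col + bb] * W[i, c, a, bb]
                out[i, r, col] = s + b[i]
    return out


def pool_oracle(x, w, mode):
    n_out = len(x) // w
    f = max if mode == "max" else (lambda win: sum(win) / len(win))
    return np.array([f(list(x[j * w : (j + 1) * w])) for j in range(n_out)])


class TestConv1d:
    def test_delta_kernel_picks_window_start(self):
        rng = np.random.default_rng(0)
        layer = Conv1d(1, 1, 3, rng, dtype=np.float64)
        layer.W[...] = np.array([[[1.0, 0.0, 0.0]]])
        layer.b[...] = 0.0
        out = layer.forward(np.array([[[1.0, 2.0, 3.0, 4.0]]]))
        assert np.allclose(out, [[[1.0, 2.0]]])

    def test_matches_loop_oracle_many_instances(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(120):
            n_c = rng.integers(1, 4)
            m = rng.integers(1, 6)
            L = rng.integers(m, m + 12)
            n_k = rng.integers(1, 4)
            layer = Conv1d(n_c, n_k, m, rng, dtype=np.float64)
            layer.b[...] = rng.normal(size=n_k)
            x = rng.normal(size=(1, n_c, L))
            got = layer.forward(x)[0]
            want = conv1d_oracle(x[0], layer.W, layer.b)
            worst = max(worst, np.max(np.abs(got - want)))
        assert worst < 1e-10

    def test_relu_saturation_with_large_negative_bias(self):
        rng = np.random.default_rng(2)
        conv = Conv1d(1, 3, 5, rng, dtype=np.float64)
        conv.b[...] = -1e6
        out = ReLU().forward(conv.forward(rng.normal(size=(2, 1, 30))))
        assert np.all(out == 0.0)

    def test_input_shorter_than_kernel_rejected(self):
        layer = Conv1d(1, 1, 5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.forward(np.zeros((1, 1, 4)))


class TestConv2d:
    def test_ones_window_sum(self):
        rng = np.random.default_rng(3)
        layer = Conv2d(1, 1, 2, 2, rng, dtype=np.float64)
        layer.W[...] = 1.0
        layer.b[...] = 0.0
        out = layer.forward(np.ones((1, 1, 3, 3)))
        assert np.allclose(out, 4.0)

    def test_identity_1x1_kernel(self):
        rng = np.random.default_rng(4)
        layer = Conv2d(1, 1, 1, 1, rng, dtype=np.float64)
        layer.W[...] = 1.0
        layer.b[...] = 0.0
        x = rng.normal(size=(2, 1, 5, 7))
        assert np.allclose(layer.forward(x), x)

    def test_matches_loop_oracle_many_instances(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(100):
            n_c = rng.integers(1, 3)
            kh, kw = rng.integers(1, 4, size=2)
            H = rng.integers(kh, kh + 5)
            W_ = rng.integers(kw, kw + 5)
            n_k = rng.integers(1, 3)
            layer = Conv2d(n_c, n_k, kh, kw, rng, dtype=np.float64)
            layer.b[...] = rng.normal(size=n_k)
            x = rng.normal(size=(1, n_c, H, W_))
            got = layer.forward(x)[0]
            want = conv2d_oracle(x[0], layer.W, layer.b)
            worst = max(worst, np.max(np.abs(got - want)))
        assert worst < 1e-10

    def test_kernel_larger_than_input_rejected(self):
        layer = Conv2d(1, 1, 4, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.forward(np.zeros((1, 1, 3, 5)))


class TestPooling:
    def test_windowed_max_example(self):
        out = Pool1d(2, "max").forward(np.array([[[1.0, 3.0, 2.0, 8.0]]]))
        assert np.allclose(out, [[[3.0, 8.0]]])

    def test_width_one_is_identity(self, rng):
        x = rng.normal(size=(2, 3, 7))
        assert np.array_equal(Pool1d(1, "max").forward(x), x)

    @pytest.mark.parametrize("mode", ["max", "avg"])
    def test_matches_loop_oracle_many_instances(self, mode):
        rng = np.random.default_rng(6)
        for _ in range(100):
            w = int(rng.integers(1, 5))
            L = int(rng.integers(w, w + 20))
            x = rng.normal(size=L)
            got = Pool1d(w, mode).forward(x[None, None, :])[0, 0]
            want = pool_oracle(x, w, mode)
            assert np.max(np.abs(got - want)) < 1e-10

    def test_remainder_dropped(self):
        out = Pool1d(2, "max").forward(np.arange(5.0)[None, None, :])
        assert out.shape[-1] == 2

    def test_pool2d_matches_blockwise_oracle(self, rng):
        x = rng.normal(size=(1, 2, 6, 8))
        got = Pool2d(2, "max").forward(x)
        for c in range(2):
            for r in range(3):
                for col in range(4):
                    block = x[0, c, 2 * r : 2 * r + 2, 2 * col : 2 * col + 2]
                    assert got[0, c, r, col] == block.max()

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            Pool1d(0)


class TestSoftmax:
    def test_symmetric_two_vector(self):
        assert np.allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_direct_evaluation(self):
        v = np.array([1.0, 2.0, 3.0])
        want = np.exp(v) / np.exp(v).sum()
        assert np.allclose(softmax(v), want, atol=1e-12)
        assert softmax(v).argmax() == 2

    def test_shift_invariance(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(softmax(v), softmax(v + 100.0), atol=1e-12)

    def test_distribution_properties_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            # moderate score gaps keep every probability strictly inside (0,1)
            # at double precision; huge gaps round the winner to exactly 1.0
            v = rng.normal(scale=rng.uniform(0.1, 3.0), size=rng.integers(2, 20))
            s = softmax(v)
            assert np.all(s > 0) and np.all(s < 1)
            assert abs(s.sum() - 1.0) < 1e-12
            assert s.argmax() == v.argmax()
        # extreme inputs still normalise without overflow
        s = softmax(np.array([1e8, -1e8, 0.0]))
        assert np.all(s >= 0) and abs(s.sum() - 1.0) < 1e-12

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([]))


@given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
@settings(deadline=None, derandomize=True)
def test_relu_nonnegative_and_idempotent(values):
    x = np.asarray(values)
    out = relu(x)
    assert np.all(out >= 0)
    assert np.array_equal(relu(out), out)


class TestDropout:
    def test_identity_in_eval_mode(self, rng):
        layer = Dropout(0.5, rng)
        x = rng.normal(size=(4, 10))
        assert np.array_equal(layer.forward(x, training=False), x)

    def test_inverted_scaling_preserves_mean(self):
        layer = Dropout(0.5, np.random.default_rng(8))
        x = np.ones((200, 200))
        out = layer.forward(x, training=True)
        kept = out[out > 0]
        assert np.allclose(kept, 2.0)  # inverted dropout rescales survivors
        assert abs(out.mean() - 1.0) < 0.02

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            Dropout(1.0, rng)


def test_shape_mismatch_names_offending_layer(rng):
    net = Network([Dense(4, 3, rng)])
    with pytest.raises(ValueError, match="layer 0 \\(Dense\\)"):
        net.forward(np.zeros((2, 5)))
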