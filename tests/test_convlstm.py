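"""Peephole ConvLSTM core: oracle equivalence, reductions, gradients."""

import numpy as np
import pytest

from uwbfall._layers import ConvLSTM1D
from uwbfall.convlstm import (
    GATES,
    ConvLSTMParams,
    ConvLSTMState,
    conv1d_same,
    convlstm_forward,
    convlstm_step,
    init_orthogonal,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _naive_conv1d(x, w):
    """Brute-force same-padded 1-D cross-correlation (nested loops)."""
    length, c_in = x.shape
    k, _, c_out = w.shape
    p = k // 2
    y = np.zeros((length, c_out))
    for pos in range(length):
        for tap in range(k):
            src = pos + tap - p
            if 0 <= src < length:
                for ci in range(c_in):
                    for co in range(c_out):
                        y[pos, co] += x[src, ci] * w[tap, ci, co]
    return y


def _naive_step(x, h, c, p):
    """Direct loop-based evaluation of the gate equations."""
    pre = lambda g: _naive_conv1d(x, p.w_x[g]) + _naive_conv1d(h, p.w_h[g]) + p.b[g]
    i_t = _sigmoid(pre("i") + p.w_c["i"] * c)
    f_t = _sigmoid(pre("f") + p.w_c["f"] * c)
    c_t = f_t * c + i_t * np.tanh(pre("c"))
    o_t = _sigmoid(pre("o") + p.w_c["o"] * c_t)
    return o_t * np.tanh(c_t), c_t


def _random_params(rng, length, c_in, c_h, k):
    p = init_orthogonal(c_in, c_h, k, spatial_length=length, seed=int(rng.integers(1 << 30)))
    for g in ("i", "f", "o"):
        p.w_c[g] = rng.standard_normal((length, c_h)) * 0.5
    for g in GATES:
        p.b[g] = rng.standard_normal(c_h) * 0.2
    return p


class TestStepAgainstNaiveOracle:
    def test_zero_weights_give_half_gates_and_zero_state(self):
        c_in, c_h, k, length = 2, 3, 3, 5
        p = init_orthogonal(c_in, c_h, k, spatial_length=length, seed=0)
        for g in GATES:
            p.w_x[g][...] = 0.0
            p.w_h[g][...] = 0.0
        x = np.ones((length, c_in))
        state = convlstm_step(x, p.zeros_state(length), p)
        assert np.allclose(state.cell, 0.0)
        assert np.allclose(state.hidden, 0.0)

    def test_matches_loop_oracle_on_many_random_instances(self):
        """Vectorized step equals the naive loop evaluation to 1e-10."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            length = int(rng.integers(3, 9))
            c_in = int(rng.integers(1, 4))
            c_h = int(rng.integers(1, 4))
            k = int(rng.choice([1, 3, 5]))
            p = _random_params(rng, length, c_in, c_h, k)
            x = rng.standard_normal((length, c_in))
            h0 = rng.standard_normal((length, c_h)) * 0.5
            c0 = rng.standard_normal((length, c_h)) * 0.5
            state = convlstm_step(x, ConvLSTMState(hidden=h0, cell=c0), p)
            h_ref, c_ref = _naive_step(x, h0, c0, p)
            worst = max(worst, np.abs(state.hidden - h_ref).max(), np.abs(state.cell - c_ref).max())
        assert worst < 1e-10

    def test_reduces_to_scalar_peephole_lstm(self):
        """kernel_width=1, spatial_length=1 is the textbook peephole LSTM."""
        rng = np.random.default_rng(3)
        p = _random_params(rng, length=1, c_in=1, c_h=1, k=1)
        wxi, whi, wci, bi = p.w_x["i"][0, 0, 0], p.w_h["i"][0, 0, 0], float(p.w_c["i"][0, 0]), p.b["i"][0]
        wxf, whf, wcf, bf = p.w_x["f"][0, 0, 0], p.w_h["f"][0, 0, 0], float(p.w_c["f"][0, 0]), p.b["f"][0]
        wxc, whc, bc = p.w_x["c"][0, 0, 0], p.w_h["c"][0, 0, 0], p.b["c"][0]
        wxo, who, wco, bo = p.w_x["o"][0, 0, 0], p.w_h["o"][0, 0, 0], float(p.w_c["o"][0, 0]), p.b["o"][0]
        h, c = 0.3, -0.2
        x = 0.7
        i = _sigmoid(wxi * x + whi * h + wci * c + bi)
        f = _sigmoid(wxf * x + whf * h + wcf * c + bf)
        c_new = f * c + i * np.tanh(wxc * x + whc * h + bc)
        o = _sigmoid(wxo * x + who * h + wco * c_new + bo)
        h_new = o * np.tanh(c_new)
        state = convlstm_step(
            np.array([[x]]), ConvLSTMState(hidden=np.array([[h]]), cell=np.array([[c]])), p
        )
        assert state.hidden[0, 0] == pytest.approx(h_new, abs=1e-12)
        assert state.cell[0, 0] == pytest.approx(c_new, abs=1e-12)

    def test_gate_outputs_stay_in_open_unit_interval(self):
        rng = np.random.default_rng(8)
        p = _random_params(rng, 6, 2, 2, 3)
        seq = rng.standard_normal((10, 6, 2)) * 3
        h = convlstm_forward(seq, p, return_last=True)
        assert np.all(np.abs(h) < 1.0)  # output-gated tanh

    def test_shape_mismatch_raises(self):
        p = init_orthogonal(2, 3, 3, spatial_length=5, seed=0)
        with pytest.raises(ValueError):
            convlstm_step(np.zeros((4, 2)), p.zeros_state(5), p)


class TestForward:
    def test_single_step_sequence_equals_one_step(self):
        rng = np.random.default_rng(5)
        p = _random_params(rng, 5, 2, 3, 3)
        x = rng.standard_normal((1, 5, 2))
        out = convlstm_forward(x, p)
        step = convlstm_step(x[0], p.zeros_state(5), p)
        assert np.array_equal(out, step.hidden)

    def test_return_last_shape(self):
        p = init_orthogonal(2, 4, 3, spatial_length=7, seed=1)
        out = convlstm_forward(np.zeros((6, 7, 2)), p, return_last=True)
        assert out.shape == (7, 4)
        full = convlstm_forward(np.zeros((6, 7, 2)), p, return_last=False)
        assert full.shape == (6, 7, 4)

    def test_empty_sequence_raises(self):
        p = init_orthogonal(2, 4, 3, spatial_length=7, seed=1)
        with pytest.raises(ValueError):
            convlstm_forward(np.zeros((0, 7, 2)), p)

    def test_constant_input_state_updates_shrink_over_time(self):
        rng = np.random.default_rng(17)
        p = _random_params(rng, 5, 2, 3, 3)
        x = np.tile(rng.standard_normal((1, 5, 2)), (30, 1, 1))
        hs = convlstm_forward(x, p, return_last=False)
        diffs = [float(np.linalg.norm(hs[t] - hs[t - 1])) for t in range(1, 30)]
        # the recurrence settles: late updates are smaller than early ones
        assert np.mean(diffs[-5:]) < np.mean(diffs[:5])


class TestInitOrthogonal:
    def test_kernel_matrices_are_orthogonal(self):
        p = init_orthogonal(4, 12, 3, spatial_length=9, seed=7)
        for g in GATES:
            for w in (p.w_x[g], p.w_h[g]):
                mat = w.reshape(-1, w.shape[-1])
                gram = mat.T @ mat
                assert np.abs(gram - np.eye(mat.shape[1])).max() < 1e-6
            assert np.all(p.b[g] == 0.0)

    def test_seed_reproducibility(self):
        a = init_orthogonal(2, 3, 3, spatial_length=5, seed=9)
        b = init_orthogonal(2, 3, 3, spatial_length=5, seed=9)
        c = init_orthogonal(2, 3, 3, spatial_length=5, seed=10)
        assert all(np.array_equal(a.w_x[g], b.w_x[g]) for g in GATES)
        assert any(not np.array_equal(a.w_x[g], c.w_x[g]) for g in GATES)


class TestTrainableLayer:
    def test_layer_forward_matches_reference_equations(self):
        rng = np.random.default_rng(13)
        layer = ConvLSTM1D(2, 3, 3, spatial_length=7, seed=5)
        for g in ("i", "f", "o"):
            layer.w_c[g][...] = rng.standard_normal((7, 3)) * 0.3
        seq = rng.standard_normal((4, 6, 7, 2))
        out = layer.forward(seq)
        ref = convlstm_forward(seq, layer.to_reference_params())
        assert np.abs(out - ref).max() < 1e-12

    def test_bptt_gradients_match_finite_differences(self):
        """Analytic BPTT vs central differences on sum(H_T^2)/2."""
        rng = np.random.default_rng(21)
        layer = ConvLSTM1D(2, 2, 3, spatial_length=5, seed=2)
        for g in ("i", "f", "o"):
            layer.w_c[g][...] = rng.standard_normal((5, 2)) * 0.3
        seq = rng.standard_normal((3, 4, 5, 2))

        def loss():
            h = layer.forward(seq)
            return 0.5 * float((h**2).sum())

        layer.zero_grads()
        h = layer.forward(seq)
        layer.backward(h.copy())
        eps, worst = 1e-6, 0.0
        for p_, g_ in layer.params_and_grads():
            flat, gflat = p_.reshape(-1), g_.reshape(-1)
            for idx in {0, flat.size // 2, flat.size - 1}:
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - gflat[idx]) / max(1e-8, abs(num) + abs(gflat[idx])))
        assert worst < 1e-4

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(30)
        layer = ConvLSTM1D(1, 2, 3, spatial_length=4, seed=6)
        seq = rng.standard_normal((2, 3, 4, 1))
        layer.zero_grads()
        h = layer.forward(seq)
        dx = layer.backward(h.copy())
        eps, worst = 1e-6, 0.0
        for idx in [(0, 0, 0, 0), (1, 2, 3, 0), (0, 1, 2, 0)]:
            old = seq[idx]
            seq[idx] = old + eps
            lp = 0.5 * float((layer.forward(seq) ** 2).sum())
            seq[idx] = old - eps
            lm = 0.5 * float((layer.forward(seq) ** 2).sum())
            seq[idx] = old
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - dx[idx]) / max(1e-8, abs(num) + abs(dx[idx])))
        assert worst < 1e-4


def test_conv1d_same_matches_naive():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((6, 3))
    w = rng.standard_normal((5, 3, 2))
    assert np.abs(conv1d_same(x, w) - _naive_conv1d(x, w)).max() < 1e-12
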