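"""LSTM building blocks: gate algebra, the modified output connection,
stacking/dropout, and the analytic input Jacobian."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lstmkf import autodiff as ad
from lstmkf.autodiff import Tensor
from lstmkf.cells import (LSTMState, LSTMWeights, ModifiedOutputParams,
                          init_lstm_weights, lstm_step,
                          lstm_step_with_jacobian, modified_output,
                          stacked_forward)
from lstmkf.errors import DimensionError, InvalidParameterError

from conftest import finite_difference_grad


def _sigm(x):
    return 1.0 / (1.0 + np.exp(-x))


def zero_weights(n_in, n_h):
    def t(shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    return LSTMWeights(t((n_h, n_h + n_in)), t((n_h, n_h + n_in)),
                       t((n_h, n_h + n_in)), t((n_h, n_h + n_in)),
                       t(n_h), t(n_h), t(n_h), t(n_h))


def naive_lstm_step(x, h_prev, C_prev, w):
    """Independent gate-by-gate evaluation on raw arrays."""
    hx = np.concatenate([h_prev, x])
    f = _sigm(w.W_f.data @ hx + w.b_f.data)
    i = _sigm(w.W_i.data @ hx + w.b_i.data)
    c = np.tanh(w.W_c.data @ hx + w.b_c.data)
    o = _sigm(w.W_o.data @ hx + w.b_o.data)
    C = f * C_prev + i * c
    return o * np.tanh(C), C


class TestLstmStep:
    def test_zero_parameters_fixed_point(self):
        w = zero_weights(3, 4)
        h, state = lstm_step(Tensor(np.ones(3)), LSTMState.zeros(4), w)
        np.testing.assert_allclose(h.data, 0.0)
        np.testing.assert_allclose(state.C.data, 0.0)

    def test_zero_weights_halve_cell_state(self):
        w = zero_weights(2, 3)
        c = np.array([0.4, -1.0, 2.0])
        state = LSTMState(Tensor(np.zeros(3)), Tensor(c))
        h, new = lstm_step(Tensor(np.zeros(2)), state, w)
        np.testing.assert_allclose(new.C.data, 0.5 * c, atol=1e-12)
        np.testing.assert_allclose(h.data, 0.5 * np.tanh(0.5 * c), atol=1e-12)

    def test_matches_naive_gate_by_gate_evaluation(self, rng):
        w = init_lstm_weights(5, 7, rng)
        x = rng.standard_normal(5)
        h_prev = rng.standard_normal(7) * 0.5
        C_prev = rng.standard_normal(7)
        h, state = lstm_step(Tensor(x), LSTMState(Tensor(h_prev), Tensor(C_prev)), w)
        h_ref, C_ref = naive_lstm_step(x, h_prev, C_prev, w)
        np.testing.assert_allclose(h.data, h_ref, atol=1e-12)
        np.testing.assert_allclose(state.C.data, C_ref, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        w = init_lstm_weights(5, 7, rng)
        with pytest.raises(DimensionError):
            lstm_step(Tensor(np.zeros(4)), LSTMState.zeros(7), w)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_hidden_output_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        w = init_lstm_weights(3, 4, rng)
        for p in w.tensors("w").values():
            p.data *= 5.0  # extreme weights still cannot break the bound
        h, state = lstm_step(Tensor(rng.standard_normal(3) * 10),
                             LSTMState(Tensor(rng.uniform(-1, 1, 4)),
                                       Tensor(rng.standard_normal(4))), w)
        assert np.all(np.abs(h.data) <= 1.0)

    def test_gradients_flow_to_all_weight_groups(self, rng):
        w = init_lstm_weights(3, 4, rng)
        x = Tensor(rng.standard_normal(3))
        state = LSTMState(Tensor(rng.standard_normal(4) * 0.1),
                          Tensor(rng.standard_normal(4)))
        h, _ = lstm_step(x, state, w)
        ad.l2norm(h).backward()
        for name, p in w.tensors("w").items():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_cell_backward_matches_finite_differences(self, rng):
        w = init_lstm_weights(2, 3, rng)
        x0 = rng.standard_normal(2)
        state0 = (rng.standard_normal(3) * 0.3, rng.standard_normal(3))

        def value(flat):
            wt = zero_weights(2, 3)
            offset = 0
            for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"):
                arr = getattr(w, name).data
                getattr(wt, name).data = flat[offset:offset + arr.size].reshape(arr.shape)
                offset += arr.size
            h, _ = lstm_step(Tensor(x0), LSTMState(Tensor(state0[0]),
                                                   Tensor(state0[1])), wt)
            return (h * h).sum().item()

        flat = np.concatenate([getattr(w, n).data.ravel()
                               for n in ("W_f", "W_i", "W_c", "W_o",
                                         "b_f", "b_i", "b_c", "b_o")])
        h, _ = lstm_step(Tensor(x0), LSTMState(Tensor(state0[0]),
                                               Tensor(state0[1])), w)
        (h * h).sum().backward()
        analytic = np.concatenate([getattr(w, n).grad.ravel()
                                   for n in ("W_f", "W_i", "W_c", "W_o",
                                             "b_f", "b_i", "b_c", "b_o")])
        fd = finite_difference_grad(value, flat)
        np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-8)


class TestInputJacobian:
    def test_matches_finite_differences(self, rng):
        w = init_lstm_weights(3, 5, rng)
        x0 = rng.standard_normal(3)
        h_prev = rng.standard_normal(5) * 0.4
        C_prev = rng.standard_normal(5)
        _, _, J = lstm_step_with_jacobian(
            Tensor(x0), LSTMState(Tensor(h_prev), Tensor(C_prev)), w)
        for i in range(5):
            fd = finite_difference_grad(
                lambda x: naive_lstm_step(x, h_prev, C_prev, w)[0][i], x0.copy())
            np.testing.assert_allclose(J.data[i], fd, rtol=1e-6, atol=1e-9)

    def test_jacobian_with_coupled_input_gate(self, rng):
        w = init_lstm_weights(2, 4, rng, couple_input_gate=True)
        x0 = rng.standard_normal(2)
        _, _, J = lstm_step_with_jacobian(Tensor(x0), LSTMState.zeros(4), w)

        def out_i(x, i):
            hx = np.concatenate([np.zeros(4), x])
            i_pre = w.W_i.data @ hx + w.b_i.data
            f = _sigm(w.W_f.data @ hx + w.b_f.data)
            ig = _sigm(i_pre)
            c = np.tanh(w.W_c.data @ hx + w.b_c.data)
            o = _sigm(w.W_o.data @ hx + w.b_o.data + i_pre)
            return (o * np.tanh(ig * c))[i]

        for i in range(4):
            fd = finite_difference_grad(lambda x: out_i(x, i), x0.copy())
            np.testing.assert_allclose(J.data[i], fd, rtol=1e-6, atol=1e-9)


class TestModifiedOutput:
    def test_identity_readout_returns_cell_state(self):
        params = ModifiedOutputParams(V=Tensor(np.eye(2)), W_direct=[], window_len=4)
        C = Tensor(np.array([0.3, -0.7]))
        np.testing.assert_allclose(modified_output(C, [], params).data, C.data)

    def test_pure_skip_connection(self):
        params = ModifiedOutputParams(V=Tensor(np.zeros((2, 2))),
                                      W_direct=[Tensor(np.eye(2))], window_len=4)
        x = Tensor(np.array([1.5, -2.0]))
        out = modified_output(Tensor(np.zeros(2)), [x], params)
        np.testing.assert_allclose(out.data, x.data)

    def test_superposition_of_state_and_skip(self):
        params = ModifiedOutputParams(V=Tensor(np.eye(2)),
                                      W_direct=[Tensor(np.eye(2))], window_len=4)
        out = modified_output(Tensor(np.array([1.0, 0.0])),
                              [Tensor(np.array([0.0, 1.0]))], params)
        np.testing.assert_allclose(out.data, [1.0, 1.0])

    def test_linearity_in_state_and_inputs(self, rng):
        params = ModifiedOutputParams(
            V=Tensor(rng.standard_normal((3, 3))),
            W_direct=[Tensor(rng.standard_normal((3, 3))) for _ in range(2)],
            window_len=4)
        C1, C2 = rng.standard_normal(3), rng.standard_normal(3)
        xs1 = [rng.standard_normal(3) for _ in range(2)]
        xs2 = [rng.standard_normal(3) for _ in range(2)]
        a, b = 1.7, -0.3
        lhs = modified_output(
            Tensor(a * C1 + b * C2),
            [Tensor(a * x1 + b * x2) for x1, x2 in zip(xs1, xs2)], params).data
        rhs = a * modified_output(Tensor(C1), [Tensor(x) for x in xs1], params).data \
            + b * modified_output(Tensor(C2), [Tensor(x) for x in xs2], params).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_long_history_truncated_with_notice(self, caplog):
        params = ModifiedOutputParams(V=Tensor(np.zeros((1, 1))),
                                      W_direct=[Tensor(np.eye(1))], window_len=2)
        history = [Tensor(np.array([float(k)])) for k in range(5)]
        with caplog.at_level(logging.INFO, logger="lstmkf.cells"):
            out = modified_output(Tensor(np.zeros(1)), history, params)
        assert out.data[0] == pytest.approx(4.0)  # most recent survives
        assert any("truncated" in r.message for r in caplog.records)

    def test_negative_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModifiedOutputParams(V=Tensor(np.eye(1)), window_len=-1)


class TestStackedForward:
    def test_keep_prob_one_training_equals_evaluation(self, rng):
        layers = [init_lstm_weights(3, 4, rng), init_lstm_weights(4, 4, rng)]
        xs = [rng.standard_normal(3) for _ in range(6)]
        train_out, _ = stacked_forward(xs, layers, keep_prob=1.0, training=True,
                                       rng=np.random.default_rng(0))
        eval_out, _ = stacked_forward(xs, layers, keep_prob=1.0, training=False)
        for a, b in zip(train_out, eval_out):
            np.testing.assert_allclose(a.data, b.data, atol=1e-15)

    def test_single_layer_reduces_to_repeated_steps(self, rng):
        w = init_lstm_weights(3, 4, rng)
        xs = [rng.standard_normal(3) for _ in range(5)]
        out, _ = stacked_forward(xs, [w])
        state = LSTMState.zeros(4)
        for x, h_stacked in zip(xs, out):
            h, state = lstm_step(Tensor(x), state, w)
            np.testing.assert_allclose(h_stacked.data, h.data, atol=1e-15)

    def test_seeded_dropout_is_reproducible(self, rng):
        layers = [init_lstm_weights(2, 6, rng)]
        xs = [rng.standard_normal(2) for _ in range(4)]
        a, _ = stacked_forward(xs, layers, keep_prob=0.7, training=True,
                               rng=np.random.default_rng(99))
        b, _ = stacked_forward(xs, layers, keep_prob=0.7, training=True,
                               rng=np.random.default_rng(99))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_dropout_requires_rng_in_training(self, rng):
        with pytest.raises(InvalidParameterError):
            stacked_forward([np.zeros(2)], [init_lstm_weights(2, 3, rng)],
                            keep_prob=0.5, training=True)

    def test_invalid_keep_prob(self, rng):
        with pytest.raises(InvalidParameterError):
            stacked_forward([np.zeros(2)], [init_lstm_weights(2, 3, rng)],
                            keep_prob=0.0)
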