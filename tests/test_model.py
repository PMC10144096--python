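"""The learned filter: module forwards, Jacobians, the reduction to the
classical KF, the loss, and end-to-end differentiability."""

import numpy as np
import pytest

from lstmkf.autodiff import Tensor
from lstmkf.cells import LSTMState
from lstmkf.errors import InvalidParameterError
from lstmkf.kalman import LinearGaussianModel, run_filter
from lstmkf.model import LSTMKF, LSTMKFConfig, sequence_loss

from conftest import finite_difference_grad


def tiny_config(**overrides):
    base = dict(state_dim=2, f_hidden=8, f_layers=1, fc_hidden=(8,),
                q_hidden=8, r_hidden=8)
    base.update(overrides)
    return LSTMKFConfig(**base)


def freeze_noise_heads(model, q_diag=1.0, r_diag=1.0):
    """Pin the Q/R modules to constant diagonals."""
    for (W, b), val in ((model.q_head, q_diag), (model.r_head, r_diag)):
        W.data[:] = 0.0
        b.data[:] = np.log(val)


def naive_forward(model, y_prev):
    """Independent layer-by-layer evaluation of the transition module."""
    def sigm(v):
        return 1.0 / (1.0 + np.exp(-v))

    x = (np.asarray(y_prev) - model.input_mean) / model.input_scale
    h_prev = [np.zeros(model.cfg.f_hidden)] * model.cfg.f_layers
    for li, w in enumerate(model.f_lstm):
        hx = np.concatenate([h_prev[li], x])
        f = sigm(w.W_f.data @ hx + w.b_f.data)
        i = sigm(w.W_i.data @ hx + w.b_i.data)
        c = np.tanh(w.W_c.data @ hx + w.b_c.data)
        o = sigm(w.W_o.data @ hx + w.b_o.data)
        x = o * np.tanh(f * 0.0 + i * c)  # zero initial cell state
    for li, (W, b) in enumerate(model.f_fc):
        x = W.data @ x + b.data
        if li < len(model.f_fc) - 1:
            x = np.maximum(x, 0.0)
    if model.cfg.residual:
        x = np.asarray(y_prev) + x
    return x


class TestPredictState:
    def test_zero_network_outputs_zero_vector(self):
        m = LSTMKF(tiny_config(), seed=0)
        for p in m.parameters().values():
            p.data[:] = 0.0
        y, _, _ = m.predict_state(Tensor(np.array([1.0, -2.0])),
                                  [LSTMState.zeros(8)])
        np.testing.assert_allclose(y.data, 0.0)

    def test_identity_bypass(self):
        m = LSTMKF(tiny_config(identity_f=True), seed=0)
        y0 = np.array([0.3, 0.7])
        y, _, F = m.predict_state(Tensor(y0), [LSTMState.zeros(8)])
        np.testing.assert_allclose(y.data, y0)
        np.testing.assert_allclose(F.data, np.eye(2))

    def test_matches_independent_layerwise_evaluation(self, rng):
        m = LSTMKF(tiny_config(f_layers=2, head_scale=0.5), seed=4)
        m.input_mean = rng.standard_normal(2)
        m.input_scale = np.array([0.5, 2.0])
        m._refresh_constants()
        y0 = rng.standard_normal(2)
        y, _, _ = m.predict_state(Tensor(y0),
                                  [LSTMState.zeros(8), LSTMState.zeros(8)])
        np.testing.assert_allclose(y.data, naive_forward(m, y0), atol=1e-10)

    def test_residual_mode_adds_input(self, rng):
        m = LSTMKF(tiny_config(residual=True, head_scale=0.5), seed=4)
        y0 = rng.standard_normal(2)
        y, _, _ = m.predict_state(Tensor(y0), [LSTMState.zeros(8)])
        np.testing.assert_allclose(y.data, naive_forward(m, y0), atol=1e-10)

    def test_non_finite_input_rejected(self):
        m = LSTMKF(tiny_config(), seed=0)
        with pytest.raises(InvalidParameterError):
            m.predict_state(Tensor(np.array([np.nan, 0.0])), [LSTMState.zeros(8)])


class TestJacobian:
    def test_identity_bypass_jacobian(self):
        m = LSTMKF(tiny_config(identity_f=True), seed=0)
        np.testing.assert_allclose(m.jacobian_of_f(np.zeros(2)), np.eye(2))

    def test_zero_network_jacobian_is_zero(self):
        m = LSTMKF(tiny_config(), seed=0)
        for p in m.parameters().values():
            p.data[:] = 0.0
        np.testing.assert_allclose(m.jacobian_of_f(np.array([1.0, 2.0])), 0.0)

    @pytest.mark.parametrize("residual,layers", [(False, 1), (False, 2), (True, 1)])
    def test_matches_central_finite_differences(self, residual, layers, rng):
        m = LSTMKF(tiny_config(residual=residual, f_layers=layers,
                               head_scale=0.5), seed=9)
        m.input_scale = np.array([0.7, 1.3])
        m._refresh_constants()
        y0 = rng.standard_normal(2)
        F = m.jacobian_of_f(y0)
        for i in range(2):
            fd = finite_difference_grad(lambda y: naive_forward(m, y)[i],
                                        y0.copy(), eps=1e-5)
            np.testing.assert_allclose(F[i], fd, rtol=1e-4, atol=1e-8)


class TestNoiseModules:
    def test_zero_network_gives_unit_diagonal(self):
        m = LSTMKF(tiny_config(), seed=0)
        for p in m.parameters().values():
            p.data[:] = 0.0
        q, _ = m.predict_Q(Tensor(np.zeros(2)), LSTMState.zeros(8))
        np.testing.assert_allclose(q.data, 1.0)

    def test_forced_raw_output_exponentiates(self):
        m = LSTMKF(tiny_config(), seed=0)
        m.q_head[0].data[:] = 0.0
        m.q_head[1].data[:] = [np.log(2.0), np.log(3.0)]
        q, _ = m.predict_Q(Tensor(np.zeros(2)), LSTMState.zeros(8))
        np.testing.assert_allclose(q.data, [2.0, 3.0], rtol=1e-12)

    def test_always_strictly_positive(self, rng):
        m = LSTMKF(tiny_config(head_scale=2.0), seed=1)
        q_state = LSTMState.zeros(8)
        r_state = LSTMState.zeros(8)
        worst = np.inf
        for _ in range(10_000):
            x = Tensor(rng.standard_normal(2) * 10 ** rng.uniform(-2, 2))
            q, q_state = m.predict_Q(x, q_state)
            r, r_state = m.predict_R(x, r_state)
            worst = min(worst, q.data.min(), r.data.min())
        assert worst > 0.0

    def test_diagonal_clamped_to_stability_range(self):
        m = LSTMKF(tiny_config(), seed=0)
        m.q_head[0].data[:] = 0.0
        m.q_head[1].data[:] = 100.0  # would exponentiate to overflow
        q, _ = m.predict_Q(Tensor(np.zeros(2)), LSTMState.zeros(8))
        np.testing.assert_allclose(q.data, 1e8)


class TestFilterStep:
    def test_reduction_to_classical_kf(self, rng):
        q_val, r_val = 0.3, 0.7
        # belief initializes at z_0 with P_0 = r * I in both implementations
        m = LSTMKF(tiny_config(identity_f=True, p0=r_val), seed=0)
        freeze_noise_heads(m, q_val, r_val)
        z = rng.standard_normal((100, 2))
        z[40:45] = np.nan  # occlusion stretch
        out = m.run(list(z))
        ref_model = LinearGaussianModel(np.eye(2), np.eye(2),
                                        q_val * np.eye(2), r_val * np.eye(2))
        ref = run_filter(ref_model, list(z))
        assert np.abs(out["means"] - ref.means).max() < 1e-6

    def test_tiny_r_tracks_measurements(self, rng):
        m = LSTMKF(tiny_config(identity_f=True), seed=0)
        freeze_noise_heads(m, 1.0, 1e-8)
        z = rng.standard_normal((20, 2))
        out = m.run(list(z))
        np.testing.assert_allclose(out["means"][1:], z[1:], atol=1e-6)

    def test_gap_frame_inflates_covariance(self, rng):
        m = LSTMKF(tiny_config(identity_f=True), seed=0)
        freeze_noise_heads(m, 0.5, 1.0)
        state = m.init_state(np.zeros(2))
        trace_prev = np.trace(state.P.data)
        _, state, _ = m.step(state, None)
        assert np.trace(state.P.data) >= trace_prev

    def test_first_frame_must_have_measurement(self):
        m = LSTMKF(tiny_config(), seed=0)
        with pytest.raises(InvalidParameterError):
            m.run([None, np.zeros(2)])


class TestSequenceLoss:
    def test_perfect_predictions_give_zero(self):
        y = [Tensor(np.array([1.0, 2.0]))]
        assert sequence_loss([y[0].data], y, y).item() == pytest.approx(0.0)

    def test_hand_arithmetic_single_frame(self):
        y_true = [np.array([0.0, 0.0])]
        y_hat = [Tensor(np.array([1.0, 0.0]))]       # error norm 1
        y_prime = [Tensor(np.array([0.0, 2.0]))]     # error norm 2
        assert sequence_loss(y_true, y_hat, y_prime, lam=0.5).item() \
            == pytest.approx(2.0)

    def test_lambda_zero_drops_prior_term(self, rng):
        y_true = [rng.standard_normal(3) for _ in range(4)]
        y_hat = [Tensor(y + 0.1) for y in y_true]
        y_prime = [Tensor(rng.standard_normal(3)) for _ in y_true]
        expected = np.mean([np.linalg.norm(0.1 * np.ones(3))] * 4)
        assert sequence_loss(y_true, y_hat, y_prime, lam=0.0).item() \
            == pytest.approx(expected)

    def test_squared_variant(self):
        y_true = [np.zeros(2)]
        y_hat = [Tensor(np.array([3.0, 4.0]))]
        y_prime = [Tensor(np.zeros(2))]
        assert sequence_loss(y_true, y_hat, y_prime, lam=1.0,
                             squared=True).item() == pytest.approx(25.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            sequence_loss([np.zeros(2)], [], [])

    def test_nonnegative_and_zero_only_when_exact(self, rng):
        for _ in range(20):
            y_true = [rng.standard_normal(2) for _ in range(3)]
            y_hat = [Tensor(y + rng.standard_normal(2) * 0.01) for y in y_true]
            y_prime = [Tensor(y) for y in y_true]
            val = sequence_loss(y_true, y_hat, y_prime).item()
            assert val > 0.0


class TestEndToEndGradient:
    @pytest.mark.parametrize("delta,alphas", [(False, ()), (True, ()),
                                              (True, (0.3, 0.05))])
    def test_backprop_through_filter_matches_finite_differences(self, delta,
                                                                alphas, rng):
        """Gradient of the mixed loss w.r.t. every parameter group, through
        the gain, covariances and Jacobian of the full filter recursion."""
        m = LSTMKF(tiny_config(head_scale=0.3, residual=True,
                               delta_features=delta, ema_alphas=alphas), seed=3)
        # evaluate at a generic parameter point: zero biases with zero inputs
        # would park FC pre-activations exactly on the ReLU kink, where the
        # linearization (hence the loss) is not differentiable
        for name, p in m.parameters().items():
            if name.endswith(("b_f", "b_i", "b_c", "b_o", ".b")):
                p.data = p.data + rng.standard_normal(p.data.shape) * 0.1
        T = 5
        z = rng.standard_normal((T, 2))
        z[3] = np.nan  # include a prediction-only frame in the graph
        y_true = rng.standard_normal((T, 2))

        def loss_value():
            state = m.init_state(z[0])
            y_hats, y_primes = [], []
            for t in range(1, T):
                z_t = None if np.all(np.isnan(z[t])) else z[t]
                y_hat, state, ex = m.step(state, z_t)
                y_hats.append(y_hat)
                y_primes.append(ex["y_prime"])
            return sequence_loss(y_true[1:], y_hats, y_primes, lam=0.7)

        loss = loss_value()
        m.zero_grad()
        loss.backward()
        grads = {k: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
                 for k, p in m.parameters().items()}
        eps = 1e-5
        for name, p in m.parameters().items():
            fd = np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p.data[idx]
                p.data[idx] = orig + eps
                up = loss_value().item()
                p.data[idx] = orig - eps
                down = loss_value().item()
                p.data[idx] = orig
                fd[idx] = (up - down) / (2 * eps)
            rel = np.linalg.norm(grads[name] - fd) / max(np.linalg.norm(fd), 1e-6)
            assert rel < 1e-3, f"{name}: relative gradient error {rel:.2e}"


class TestPersistence:
    def test_save_load_reproduces_filter_output(self, tmp_path, rng):
        m = LSTMKF(tiny_config(residual=True), seed=5)
        m.fit_input_scaler([rng.standard_normal((50, 2))])
        z = rng.standard_normal((30, 2))
        before = m.run(list(z))["means"]
        m.save(str(tmp_path / "ckpt"))
        loaded = LSTMKF.load(str(tmp_path / "ckpt"))
        after = loaded.run(list(z))["means"]
        np.testing.assert_array_equal(before, after)
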