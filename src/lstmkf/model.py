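"""The LSTM-KF: a Kalman filter whose internals are predicted by LSTMs.

Classical filtering requires the modeler to specify the transition
function and the noise covariances a priori.  Here three recurrent modules
learn them from data and feed them into the filter equations each frame:

* ``LSTM_f`` — takes the previous posterior mean y_{t-1} and produces the
  transition prediction y'_t (stacked LSTM layers + a fully connected
  stack, ReLU on all FC activations except the last);
* ``LSTM_Q`` — takes y'_t and emits the diagonal process-noise covariance
  Q_t (positivity enforced by exponentiating the raw output);
* ``LSTM_R`` — takes the measurement z_t and emits the diagonal
  measurement-noise covariance R_t.

The filter then runs the extended-KF recursion with H = I:

    y'_t = f(y_{t-1})                   P'_t = F P_{t-1} F^T + Q_t
    K_t  = P'_t (P'_t + R_t)^-1
    y_t  = y'_t + K_t (z_t - y'_t)      P_t = (I - K_t) P'_t

where F is the Jacobian of f at y_{t-1}, assembled analytically on the
autodiff tape so the whole recursion — gain, covariances and all — is
differentiable end to end.  Frames with no measurement (occlusion,
dropped detection) return the prior (y'_t, P'_t) unchanged.

The training loss mixes the posterior and prior errors,

    L = (1/T) sum_t ( ||y_t - y^_t||_2 + lambda ||y_t - y'_t||_2 ),

the second term feeding gradient directly to the transition module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cells import LSTMState, LSTMWeights, init_lstm_weights, lstm_step, \
    lstm_step_with_jacobian
from .errors import DimensionError, InvalidParameterError

__all__ = ["LSTMKFConfig", "LSTMKFState", "LSTMKF", "sequence_loss", "FULL_SCALE_CONFIG"]

_LOG_CLAMP = np.log(1e8)  # covariance diagonals clamped to [1e-8, 1e8]


@dataclass
class LSTMKFConfig:
    """Architecture and loss constants of the three recurrent modules.

    The full-scale profile (3x1024 recurrent + 1024/1024/out FC for the
    transition module, 256-unit monolayers for the noise modules, dropout
    retention 0.7) is available as :data:`FULL_SCALE_CONFIG`; the default here
    is a desk-scale profile suitable for CPU training.
    """

    state_dim: int = 3
    f_hidden: int = 64
    f_layers: int = 3
    fc_hidden: tuple = (64, 64)
    q_hidden: int = 32
    r_hidden: int = 32
    keep_prob: float = 1.0
    lam: float = 1.0
    squared_loss: bool = False
    residual: bool = False
    identity_f: bool = False
    couple_input_gate: bool = False
    delta_features: bool = False
    ema_alphas: tuple = ()  # EMA displacement features (delta mode only)
    direct_skip: bool = False  # linear feature-to-output connection for f
    p0: float = 1.0
    q_bias_init: float = 0.0
    r_bias_init: float = 0.0
    head_scale: float = 1e-3

    def __post_init__(self):
        if self.state_dim < 1 or self.f_hidden < 1 or self.q_hidden < 1 or self.r_hidden < 1:
            raise InvalidParameterError("layer sizes must be >= 1")
        if self.lam < 0:
            raise InvalidParameterError("lambda must be >= 0")
        if not (0.0 < self.keep_prob <= 1.0):
            raise InvalidParameterError("keep_prob must be in (0, 1]")


#: Full-scale architecture profile (48-dim output as used for multi-joint pose).
FULL_SCALE_CONFIG = LSTMKFConfig(
    state_dim=48, f_hidden=1024, f_layers=3, fc_hidden=(1024, 1024),
    q_hidden=256, r_hidden=256, keep_prob=0.7,
)


@dataclass
class LSTMKFState:
    """Recurrent states of the three modules plus the current belief.

    ``y_prev`` and ``z_prev`` carry the previous posterior and the last
    seen measurement, used by the displacement-feature mode.
    """

    f_states: list
    q_state: LSTMState
    r_state: LSTMState
    y: Tensor
    P: Tensor
    y_prev: Tensor = None
    z_prev: Tensor = None
    ema_y: list = None  # EMA-smoothed state displacements, one per timescale
    ema_z: list = None  # EMA-smoothed measurement displacements

    def detach(self) -> "LSTMKFState":
        """Cut the tape (TBPTT window boundary); values carry over."""
        return LSTMKFState(
            [s.detach() for s in self.f_states],
            self.q_state.detach(),
            self.r_state.detach(),
            self.y.detach(),
            self.P.detach(),
            self.y_prev.detach() if self.y_prev is not None else None,
            self.z_prev.detach() if self.z_prev is not None else None,
            [e.detach() for e in self.ema_y] if self.ema_y is not None else None,
            [e.detach() for e in self.ema_z] if self.ema_z is not None else None,
        )


def _init_linear(n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None, bias: float = 0.0):
    bound = scale if scale is not None else 1.0 / np.sqrt(n_in)
    W = Tensor(rng.uniform(-bound, bound, size=(n_out, n_in)), requires_grad=True)
    b = Tensor(np.full(n_out, bias, dtype=np.float64), requires_grad=True)
    return W, b


class LSTMKF:
    """Learned Kalman filter over a ``state_dim``-dimensional tracked state."""

    def __init__(self, cfg: LSTMKFConfig | None = None, seed: int = 0):
        self.cfg = cfg or LSTMKFConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        d = c.state_dim
        n_feat = self.feature_dim

        self.f_lstm: list[LSTMWeights] = []
        n_in = n_feat
        for _ in range(c.f_layers):
            self.f_lstm.append(init_lstm_weights(
                n_in, c.f_hidden, rng, couple_input_gate=c.couple_input_gate))
            n_in = c.f_hidden
        self.f_fc: list[tuple[Tensor, Tensor]] = []
        sizes = [c.f_hidden, *c.fc_hidden, d]
        for li in range(len(sizes) - 1):
            last = li == len(sizes) - 2
            self.f_fc.append(_init_linear(
                sizes[li], sizes[li + 1], rng,
                scale=c.head_scale if last else None))

        # optional direct linear connection from the input features to the
        # predicted displacement (the modified-output idea: skip weights
        # from inputs to outputs).  Initialized to read out the slowest EMA
        # displacement block, i.e. smoothed constant-velocity extrapolation.
        self.f_skip: Tensor | None = None
        if c.direct_skip and c.delta_features and c.ema_alphas:
            W0 = np.zeros((d, n_feat))
            W0[:, n_feat - d:] = np.eye(d)
            self.f_skip = Tensor(W0, requires_grad=True)

        self.q_lstm = init_lstm_weights(n_feat, c.q_hidden, rng,
                                        couple_input_gate=c.couple_input_gate)
        self.q_head = _init_linear(c.q_hidden, d, rng, scale=c.head_scale,
                                   bias=c.q_bias_init)
        self.r_lstm = init_lstm_weights(self.r_feature_dim, c.r_hidden, rng,
                                        couple_input_gate=c.couple_input_gate)
        self.r_head = _init_linear(c.r_hidden, d, rng, scale=c.head_scale,
                                   bias=c.r_bias_init)

        # input standardization (identity until fitted on training data);
        # increment_scale standardizes displacement features in delta mode
        self.input_mean = np.zeros(d)
        self.input_scale = np.ones(d)
        self.increment_scale = np.ones(d)
        self.z_increment_scale = np.ones(d)
        # multiplicative output scales of the covariance heads (method-of-
        # moments anchors set by fit_input_scaler; identity until fitted)
        self.q_out_scale = np.ones(d)
        self.r_out_scale = np.ones(d)
        self._refresh_constants()

    def _refresh_constants(self) -> None:
        d = self.cfg.state_dim
        self._eye = Tensor(np.eye(d))
        self._half = Tensor(0.5)
        self._mean_t = Tensor(self.input_mean)
        self._inv_scale_t = Tensor(1.0 / self.input_scale)
        self._scale_jac = Tensor(np.diag(1.0 / self.input_scale))
        self._inv_inc_t = Tensor(1.0 / self.increment_scale)
        self._inc_t = Tensor(self.increment_scale)
        self._inc_diag_t = Tensor(np.diag(self.increment_scale))
        self._inc_jac = Tensor(np.diag(1.0 / self.increment_scale))
        self._inv_z_inc_t = Tensor(1.0 / self.z_increment_scale)
        self._q_out_t = Tensor(self.q_out_scale)
        self._r_out_t = Tensor(self.r_out_scale)
        if self.cfg.delta_features and self.cfg.ema_alphas:
            # d(features)/dy_{t-1}: the raw displacement block plus one
            # alpha-scaled block per EMA timescale (previous EMAs held fixed)
            blocks = [np.diag(1.0 / self.increment_scale)]
            blocks += [a * np.diag(1.0 / self.increment_scale)
                       for a in self.cfg.ema_alphas]
            self._feat_jac = Tensor(np.vstack(blocks))
        else:
            self._feat_jac = self._inc_jac

    @property
    def feature_dim(self) -> int:
        """Input width of the transition/process modules: the displacement
        plus one EMA displacement block per timescale."""
        c = self.cfg
        if c.delta_features and c.ema_alphas:
            return c.state_dim * (1 + len(c.ema_alphas))
        return c.state_dim

    @property
    def r_feature_dim(self) -> int:
        """Input width of the measurement-noise module: the innovation, its
        magnitude, and one EMA magnitude block per timescale."""
        c = self.cfg
        if c.delta_features and c.ema_alphas:
            return c.state_dim * (2 + len(c.ema_alphas))
        return c.state_dim

    # -- parameter plumbing ---------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for li, w in enumerate(self.f_lstm):
            params.update(w.tensors(f"f.lstm{li}"))
        for li, (W, b) in enumerate(self.f_fc):
            params[f"f.fc{li}.W"] = W
            params[f"f.fc{li}.b"] = b
        if self.f_skip is not None:
            params["f.skip.W"] = self.f_skip
        params.update(self.q_lstm.tensors("q.lstm"))
        params["q.head.W"], params["q.head.b"] = self.q_head
        params.update(self.r_lstm.tensors("r.lstm"))
        params["r.head.W"], params["r.head.b"] = self.r_head
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def fit_input_scaler(self, sequences: Sequence[np.ndarray],
                         measurements: Sequence[np.ndarray] | None = None) -> None:
        """Standardize module inputs to the training data's per-axis scale.

        Absolute-coordinate statistics feed the default input features;
        per-frame displacement statistics (from the state sequences, and
        from ``measurements`` when given) feed the delta-feature mode.
        """
        arrays = [np.asarray(s, dtype=np.float64).reshape(-1, self.cfg.state_dim)
                  for s in sequences]
        stacked = np.concatenate(arrays)
        stacked = stacked[np.all(np.isfinite(stacked), axis=1)]
        self.input_mean = stacked.mean(axis=0)
        self.input_scale = np.maximum(stacked.std(axis=0), 1e-6)
        incs = np.concatenate([np.diff(a, axis=0) for a in arrays])
        incs = incs[np.all(np.isfinite(incs), axis=1)]
        if len(incs):
            self.increment_scale = np.maximum(incs.std(axis=0), 1e-9)
        z_arrays = arrays if measurements is None else [
            np.asarray(z, dtype=np.float64).reshape(-1, self.cfg.state_dim)
            for z in measurements]
        z_incs = np.concatenate([np.diff(a, axis=0) for a in z_arrays])
        z_incs = z_incs[np.all(np.isfinite(z_incs), axis=1)]
        if len(z_incs):
            self.z_increment_scale = np.maximum(z_incs.std(axis=0), 1e-9)
        # anchor the covariance heads at moment estimates: the measurement
        # increment variance is var(dy) + 2 sigma^2, so its excess over the
        # state increment variance estimates the average noise level; the
        # state increment variance bounds the process noise of a transition
        # no better than the identity
        if len(incs) and len(z_incs):
            var_dy = incs.var(axis=0)
            var_dz = z_incs.var(axis=0)
            self.r_out_scale = np.maximum((var_dz - var_dy) / 2.0, 1e-6)
            self.q_out_scale = np.maximum(var_dy, 1e-6)
        self._refresh_constants()

    def _scale_in(self, x: Tensor) -> Tensor:
        return (x - self._mean_t) * self._inv_scale_t

    # -- state ----------------------------------------------------------

    def init_state(self, z0: np.ndarray) -> LSTMKFState:
        """Belief initialized at the first measurement with P_0 = p0 * I."""
        d = self.cfg.state_dim
        z0 = np.asarray(z0, dtype=np.float64).reshape(d)
        n_ema = len(self.cfg.ema_alphas)
        return LSTMKFState(
            [LSTMState.zeros(self.cfg.f_hidden) for _ in range(self.cfg.f_layers)],
            LSTMState.zeros(self.cfg.q_hidden),
            LSTMState.zeros(self.cfg.r_hidden),
            Tensor(z0.copy()),
            Tensor(self.cfg.p0 * np.eye(d)),
            y_prev=Tensor(z0.copy()),
            z_prev=Tensor(z0.copy()),
            ema_y=[Tensor(np.zeros(d)) for _ in range(n_ema)],
            ema_z=[Tensor(np.zeros(d)) for _ in range(n_ema)],
        )

    # -- module forwards -------------------------------------------------

    def predict_state(self, y_prev: Tensor, f_states: list,
                      training: bool = False,
                      rng: np.random.Generator | None = None,
                      y_prev_prev: Tensor | None = None,
                      features: Tensor | None = None
                      ) -> tuple[Tensor, list, Tensor]:
        """Transition prediction y'_t and its Jacobian F w.r.t. y_{t-1}.

        The Jacobian is composed layer by layer from tape primitives, so F
        (and everything the filter derives from it) stays differentiable
        with respect to the module parameters.  In delta-feature mode the
        module consumes the standardized previous displacement
        (y_{t-1} - y_{t-2}) and predicts the next displacement, added onto
        y_{t-1} — a translation-invariant transition.
        """
        if not np.all(np.isfinite(y_prev.data)):
            raise InvalidParameterError("non-finite state input")
        d = self.cfg.state_dim
        if y_prev.shape != (d,):
            raise DimensionError(f"expected state of length {d}")
        if self.cfg.identity_f:
            return y_prev, f_states, Tensor(np.eye(d))

        keep = self.cfg.keep_prob
        if self.cfg.delta_features:
            if features is not None:
                h = features
            else:
                prev2 = y_prev_prev if y_prev_prev is not None else y_prev
                dy = (y_prev - prev2) * self._inv_inc_t
                if self.cfg.ema_alphas:
                    zeros = Tensor(np.zeros(d))
                    h = ad.concat([dy] + [zeros] * len(self.cfg.ema_alphas))
                else:
                    h = dy
            J = self._feat_jac
        else:
            h = self._scale_in(y_prev)
            J = self._scale_jac
        feats0 = h
        new_states = []
        for li, w in enumerate(self.f_lstm):
            h, new_state, J_layer = lstm_step_with_jacobian(h, f_states[li], w)
            new_states.append(new_state)
            J = J_layer @ J
            if training and keep < 1.0:
                mask = Tensor((rng.random(h.shape) < keep) / keep)
                h = h * mask
                J = ad.scale_rows(mask, J)
        for li, (W, b) in enumerate(self.f_fc):
            z = W @ h + b
            if li < len(self.f_fc) - 1:
                mask = Tensor((z.data > 0).astype(np.float64))
                h = ad.relu(z)
                J = ad.scale_rows(mask, W) @ J
            else:
                h = z
                J = W @ J
        if self.cfg.delta_features:
            if self.f_skip is not None:
                h = h + self.f_skip @ feats0
                J = J + self.f_skip @ self._feat_jac
            # network predicts the next displacement in standardized units
            y_prime = y_prev + h * self._inc_t
            F = self._eye + self._inc_diag_t @ J
        elif self.cfg.residual:
            y_prime = y_prev + h
            F = self._eye + J
        else:
            y_prime = h
            F = J
        return y_prime, new_states, F

    def _noise_module(self, x_scaled: Tensor, state: LSTMState, lstm: LSTMWeights,
                      head: tuple[Tensor, Tensor], out_scale: Tensor
                      ) -> tuple[Tensor, LSTMState]:
        h, new_state = lstm_step(x_scaled, state, lstm)
        raw = head[0] @ h + head[1]
        diag = ad.exp(ad.clip(raw, -_LOG_CLAMP, _LOG_CLAMP)) * out_scale
        return diag, new_state

    def _with_emas(self, x: Tensor, emas: list | None) -> Tensor:
        if not self.cfg.ema_alphas:
            return x
        if emas is None:
            emas = [Tensor(np.zeros(self.cfg.state_dim))] * len(self.cfg.ema_alphas)
        return ad.concat([x] + list(emas))

    def predict_Q(self, y_prime: Tensor, q_state: LSTMState,
                  y_prev: Tensor | None = None,
                  emas: list | None = None) -> tuple[Tensor, LSTMState]:
        """Diagonal of the process-noise covariance (strictly positive).

        Input is the transition prediction y'_t; in delta-feature mode the
        module sees the standardized predicted displacement y'_t - y_{t-1}
        (plus the EMA displacement features when configured).
        """
        if self.cfg.delta_features:
            prev = y_prev if y_prev is not None else y_prime
            x = self._with_emas((y_prime - prev) * self._inv_inc_t, emas)
        else:
            x = self._scale_in(y_prime)
        return self._noise_module(x, q_state, self.q_lstm, self.q_head,
                                  self._q_out_t)

    def predict_R(self, z: Tensor, r_state: LSTMState,
                  z_prev: Tensor | None = None,
                  emas: list | None = None) -> tuple[Tensor, LSTMState]:
        """Diagonal of the measurement-noise covariance (strictly positive).

        Input is the measurement z_t; in delta-feature mode the module sees
        the standardized measurement innovation z_t - z_{last seen}, its
        magnitude, and (when configured) EMA magnitude features — running
        statistics of the local noise level.
        """
        if self.cfg.delta_features:
            prev = z_prev if z_prev is not None else z
            dz = (z - prev) * self._inv_z_inc_t
            if self.cfg.ema_alphas:
                if emas is None:
                    emas = [Tensor(np.zeros(self.cfg.state_dim))] * \
                        len(self.cfg.ema_alphas)
                x = ad.concat([dz, ad.absval(dz)] + list(emas))
            else:
                x = dz
        else:
            x = self._scale_in(z)
        return self._noise_module(x, r_state, self.r_lstm, self.r_head,
                                  self._r_out_t)

    def jacobian_of_f(self, y_prev: np.ndarray,
                      f_states: list | None = None) -> np.ndarray:
        """F[i, j] = d f_i / d y_j at ``y_prev`` (fresh zero recurrent state
        unless ``f_states`` is given); plain array for inspection."""
        if f_states is None:
            f_states = [LSTMState.zeros(self.cfg.f_hidden)
                        for _ in range(self.cfg.f_layers)]
        _, _, F = self.predict_state(Tensor(np.asarray(y_prev, dtype=np.float64)),
                                     f_states)
        return F.data.copy()

    # -- the filter step -------------------------------------------------

    def step(self, state: LSTMKFState, z: np.ndarray | None,
             training: bool = False,
             rng: np.random.Generator | None = None,
             y_input: Tensor | None = None
             ) -> tuple[Tensor, LSTMKFState, dict]:
        """One frame of the learned filter.

        ``z`` is the measurement vector or ``None`` for a gap frame (the
        prior is returned unchanged).  ``y_input`` optionally overrides the
        transition module's input (teacher forcing with the true previous
        state during training).  Returns the posterior mean, the advanced
        state, and a diagnostics dict with the prior mean and the predicted
        covariance diagonals.
        """
        d = self.cfg.state_dim
        cfg = self.cfg
        eye = self._eye
        y_in = state.y if y_input is None else y_input

        features = None
        ema_y = state.ema_y
        if cfg.delta_features:
            dy = (y_in - state.y_prev) * self._inv_inc_t
            if cfg.ema_alphas:
                ema_y = [Tensor(1.0 - a) * e + Tensor(a) * dy
                         for a, e in zip(cfg.ema_alphas, state.ema_y)]
                features = ad.concat([dy] + ema_y)
            else:
                features = dy
        y_prime, f_states, F = self.predict_state(y_in, state.f_states,
                                                  training=training, rng=rng,
                                                  y_prev_prev=state.y_prev,
                                                  features=features)
        q_diag, q_state = self.predict_Q(y_prime, state.q_state, y_prev=y_in,
                                         emas=ema_y)
        P_prior = F @ state.P @ F.T + q_diag * eye

        extras = {"y_prime": y_prime, "q_diag": q_diag, "r_diag": None}
        if z is None:
            new = LSTMKFState(f_states, q_state, state.r_state, y_prime,
                              P_prior, y_prev=y_in, z_prev=state.z_prev,
                              ema_y=ema_y, ema_z=state.ema_z)
            return y_prime, new, extras

        z_t = Tensor(np.asarray(z, dtype=np.float64).reshape(d))
        ema_z = state.ema_z
        if cfg.delta_features and cfg.ema_alphas:
            abs_dz = ad.absval((z_t - state.z_prev) * self._inv_z_inc_t)
            ema_z = [Tensor(1.0 - a) * e + Tensor(a) * abs_dz
                     for a, e in zip(cfg.ema_alphas, state.ema_z)]
        r_diag, r_state = self.predict_R(z_t, state.r_state,
                                         z_prev=state.z_prev, emas=ema_z)
        extras["r_diag"] = r_diag
        K = P_prior @ ad.inv(P_prior + r_diag * eye)
        y_post = y_prime + K @ (z_t - y_prime)
        P_post = (eye - K) @ P_prior
        P_post = (P_post + P_post.T) * self._half
        new = LSTMKFState(f_states, q_state, r_state, y_post, P_post,
                          y_prev=y_in, z_prev=z_t, ema_y=ema_y, ema_z=ema_z)
        return y_post, new, extras

    def run(self, z_seq: Sequence, training: bool = False,
            rng: np.random.Generator | None = None) -> dict:
        """Filter a full measurement sequence (NaN rows / None = gaps).

        The belief initializes at the first measured frame.  Returns arrays
        of posterior means, prior means, covariance diagonals, and the
        predicted Q/R diagonals per frame (NaN where not produced).
        """
        d = self.cfg.state_dim
        z_list = [None if (z is None or np.all(np.isnan(np.asarray(z, dtype=np.float64))))
                  else np.asarray(z, dtype=np.float64).reshape(d) for z in z_seq]
        if len(z_list) == 0 or z_list[0] is None:
            raise InvalidParameterError("first frame must carry a measurement")
        T = len(z_list)
        state = self.init_state(z_list[0])
        means = np.empty((T, d))
        priors = np.empty((T, d))
        p_diag = np.empty((T, d))
        q_out = np.full((T, d), np.nan)
        r_out = np.full((T, d), np.nan)
        means[0] = priors[0] = state.y.data
        p_diag[0] = np.diag(state.P.data)
        with ad.no_grad():
            for t in range(1, T):
                y_post, state, extras = self.step(state, z_list[t],
                                                  training=training, rng=rng)
                means[t] = y_post.data
                priors[t] = extras["y_prime"].data
                p_diag[t] = np.diag(state.P.data)
                q_out[t] = extras["q_diag"].data
                if extras["r_diag"] is not None:
                    r_out[t] = extras["r_diag"].data
        return {"means": means, "priors": priors, "P_diag": p_diag,
                "Q_diag": q_out, "R_diag": r_out}

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint = config JSON + parameter/scaler arrays (.npz)."""
        params = {k: p.data for k, p in self.parameters().items()}
        params["__input_mean"] = self.input_mean
        params["__input_scale"] = self.input_scale
        params["__increment_scale"] = self.increment_scale
        params["__z_increment_scale"] = self.z_increment_scale
        params["__q_out_scale"] = self.q_out_scale
        params["__r_out_scale"] = self.r_out_scale
        np.savez(path if str(path).endswith(".npz") else f"{path}.npz", **params)
        cfg_path = str(path).removesuffix(".npz") + ".json"
        with open(cfg_path, "w") as fh:
            json.dump({"config": asdict(self.cfg)}, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "LSTMKF":
        base = str(path).removesuffix(".npz")
        with open(base + ".json") as fh:
            cfg_dict = json.load(fh)["config"]
        cfg_dict["fc_hidden"] = tuple(cfg_dict["fc_hidden"])
        cfg_dict["ema_alphas"] = tuple(cfg_dict.get("ema_alphas", ()))
        model = cls(LSTMKFConfig(**cfg_dict))
        with np.load(base + ".npz") as data:
            params = model.parameters()
            for k, p in params.items():
                p.data = np.array(data[k], dtype=np.float64)
            model.input_mean = np.array(data["__input_mean"], dtype=np.float64)
            model.input_scale = np.array(data["__input_scale"], dtype=np.float64)
            model.increment_scale = np.array(data["__increment_scale"],
                                             dtype=np.float64)
            model.z_increment_scale = np.array(data["__z_increment_scale"],
                                               dtype=np.float64)
            model.q_out_scale = np.array(data["__q_out_scale"], dtype=np.float64)
            model.r_out_scale = np.array(data["__r_out_scale"], dtype=np.float64)
        model._refresh_constants()
        return model


def sequence_loss(y_true_seq: Sequence, y_hat_seq: Sequence[Tensor],
                  y_hat_prime_seq: Sequence[Tensor], lam: float = 1.0,
                  squared: bool = False) -> Tensor:
    """L = (1/T) sum_t ( ||y_t - y^_t||_2 + lambda ||y_t - y'_t||_2 ).

    ``squared=True`` switches both terms to squared Euclidean norms.
    """
    T = len(y_true_seq)
    if T < 1 or len(y_hat_seq) != T or len(y_hat_prime_seq) != T:
        raise InvalidParameterError("sequences must have equal length T >= 1")
    total = Tensor(0.0)
    for y_true, y_hat, y_prime in zip(y_true_seq, y_hat_seq, y_hat_prime_seq):
        y_t = y_true if isinstance(y_true, Tensor) else Tensor(y_true)
        e1 = ad.l2norm(y_t - y_hat)
        e2 = ad.l2norm(y_t - y_prime)
        if squared:
            e1 = e1 * e1
            e2 = e2 * e2
        total = total + e1 + Tensor(lam) * e2
    return total / float(T)
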