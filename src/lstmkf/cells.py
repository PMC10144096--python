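"""LSTM sequence-processing building blocks on the autodiff tape.

The standard cell:

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)          forget gate
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)          input gate
    C~_t = tanh(W_c [h_{t-1}, x_t] + b_c)          candidate state
    C_t = f_t * C_{t-1} + i_t * C~_t               cell update
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)          output gate
    h_t = o_t * tanh(C_t)

plus two variants used by the tracking models: a *modified output*
connection Y_t = V C_t + sum_n W_n x_{t-n} that adds direct, lag-indexed
skip connections from a bounded window of past inputs to the output (an
overfitting-control device for small datasets), and an optional coupling of
the input gate's pre-activation into the output gate.

Each step can also return the analytic Jacobian dh_t/dx_t as a tape tensor
(built from the same gate values via the chain rule), so that an extended
Kalman filter's linearization F remains differentiable end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigm  # overflow-safe logistic

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DimensionError, InvalidParameterError

__all__ = [
    "LSTMWeights",
    "LSTMState",
    "ModifiedOutputParams",
    "init_lstm_weights",
    "lstm_step",
    "lstm_step_with_jacobian",
    "modified_output",
    "stacked_forward",
]

logger = logging.getLogger(__name__)


@dataclass
class LSTMWeights:
    """Gate weights over the concatenated [h_{t-1}, x_t] plus biases."""

    W_f: Tensor
    W_i: Tensor
    W_c: Tensor
    W_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_c: Tensor
    b_o: Tensor
    couple_input_gate: bool = False

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def tensors(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.{name}": getattr(self, name)
            for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o")
        }


@dataclass
class LSTMState:
    """Hidden vector h and cell state C of one layer."""

    h: Tensor
    C: Tensor

    @classmethod
    def zeros(cls, n_hidden: int) -> "LSTMState":
        return cls(Tensor(np.zeros(n_hidden)), Tensor(np.zeros(n_hidden)))

    def detach(self) -> "LSTMState":
        return LSTMState(self.h.detach(), self.C.detach())


def init_lstm_weights(n_in: int, n_hidden: int, rng: np.random.Generator,
                      couple_input_gate: bool = False,
                      forget_bias: float = 1.0) -> LSTMWeights:
    """Uniform(+-1/sqrt(n_hidden)) gate weights; forget bias offset for memory retention."""
    bound = 1.0 / np.sqrt(n_hidden)

    def w():
        return Tensor(rng.uniform(-bound, bound, size=(n_hidden, n_hidden + n_in)),
                      requires_grad=True)

    def b(offset=0.0):
        return Tensor(np.full(n_hidden, offset), requires_grad=True)

    return LSTMWeights(w(), w(), w(), w(), b(forget_bias), b(), b(), b(),
                       couple_input_gate=couple_input_gate)


def _fused_cell(x: Tensor, state: LSTMState, w: LSTMWeights) -> Tensor:
    """One LSTM timestep as a single tape node.

    Returns a (6, n_hidden) tensor stacking [h_t; C_t; f_t; i_t; C~_t; o_t];
    the hand-derived backward routes incoming gradients on any of the six
    rows to all eleven parents (x, h_{t-1}, C_{t-1}, the four gate weight
    matrices and biases).  Fusing the cell keeps the unrolled sequence tape
    short, which dominates CPU training cost.
    """
    if x.shape[-1] != w.input_size:
        raise DimensionError(
            f"input size {x.shape[-1]} != expected {w.input_size}")
    h_prev, C_prev = state.h.data, state.C.data
    hx = np.concatenate([h_prev, x.data])
    i_pre = w.W_i.data @ hx + w.b_i.data
    o_pre = w.W_o.data @ hx + w.b_o.data
    if w.couple_input_gate:
        o_pre = o_pre + i_pre
    f = _sigm(w.W_f.data @ hx + w.b_f.data)
    i = _sigm(i_pre)
    c_tilde = np.tanh(w.W_c.data @ hx + w.b_c.data)
    o = _sigm(o_pre)
    C_new = f * C_prev + i * c_tilde
    tC = np.tanh(C_new)
    h_new = o * tC

    parents = (x, state.h, state.C, w.W_f, w.W_i, w.W_c, w.W_o,
               w.b_f, w.b_i, w.b_c, w.b_o)
    req = ad.grad_enabled() and any(p.requires_grad for p in parents)
    out = Tensor(np.stack([h_new, C_new, f, i, c_tilde, o]), req,
                 parents if req else ())
    if req:
        n_h = w.hidden_size

        def _bw(g):
            gh, gC_ext, gf_ext, gi_ext, gc_ext, go_ext = g
            go = gh * tC + go_ext
            gC = gC_ext + gh * o * (1.0 - tC * tC)
            gf = gC * C_prev + gf_ext
            gi = gC * c_tilde + gi_ext
            gc = gC * i + gc_ext
            dpre_o = go * o * (1.0 - o)
            dpre_f = gf * f * (1.0 - f)
            dpre_i = gi * i * (1.0 - i)
            if w.couple_input_gate:
                dpre_i = dpre_i + dpre_o
            dpre_c = gc * (1.0 - c_tilde * c_tilde)
            ghx = (w.W_f.data.T @ dpre_f + w.W_i.data.T @ dpre_i
                   + w.W_c.data.T @ dpre_c + w.W_o.data.T @ dpre_o)
            if x.requires_grad:
                x._accumulate(ghx[n_h:])
            if state.h.requires_grad:
                state.h._accumulate(ghx[:n_h])
            if state.C.requires_grad:
                state.C._accumulate(gC * f)
            for W, b, dpre in ((w.W_f, w.b_f, dpre_f), (w.W_i, w.b_i, dpre_i),
                               (w.W_c, w.b_c, dpre_c), (w.W_o, w.b_o, dpre_o)):
                if W.requires_grad:
                    W._accumulate(dpre[:, None] * hx[None, :])
                if b.requires_grad:
                    b._accumulate(dpre)
        out._backward = _bw
    return out


def lstm_step(x: Tensor, state: LSTMState, w: LSTMWeights) -> tuple[Tensor, LSTMState]:
    """Advance one timestep; returns (h_t, new state)."""
    cell = _fused_cell(x, state, w)
    h_new, C_new = cell[0], cell[1]
    return h_new, LSTMState(h_new, C_new)


def lstm_step_with_jacobian(
    x: Tensor, state: LSTMState, w: LSTMWeights
) -> tuple[Tensor, LSTMState, Tensor]:
    """As :func:`lstm_step`, additionally returning J = dh_t/dx_t.

    The Jacobian is assembled from the gate values by the chain rule
    (holding h_{t-1}, C_{t-1} fixed, the extended-KF convention) using tape
    primitives only, so gradients of any function of J flow back into the
    weights.  Shape (n_hidden, n_in).
    """
    cell = _fused_cell(x, state, w)
    h_new, C_new = cell[0], cell[1]
    f, i, c_tilde, o = cell[2], cell[3], cell[4], cell[5]
    tanh_C = ad.tanh(C_new)

    n_h = w.hidden_size
    Wf_x = w.W_f[:, n_h:]
    Wi_x = w.W_i[:, n_h:]
    Wc_x = w.W_c[:, n_h:]
    Wo_x = w.W_o[:, n_h:]
    if w.couple_input_gate:
        Wo_x = Wo_x + Wi_x

    dC_dx = (
        ad.scale_rows(state.C * ad.sigmoid_deriv(f), Wf_x)
        + ad.scale_rows(c_tilde * ad.sigmoid_deriv(i), Wi_x)
        + ad.scale_rows(i * ad.tanh_deriv(c_tilde), Wc_x)
    )
    J = ad.scale_rows(tanh_C * ad.sigmoid_deriv(o), Wo_x) \
        + ad.scale_rows(o * ad.tanh_deriv(tanh_C), dC_dx)
    return h_new, LSTMState(h_new, C_new), J


@dataclass
class ModifiedOutputParams:
    """Parameters of Y_t = V C_t + sum_n W_n x_{t-n} over a bounded lag window.

    ``W_direct[k]`` multiplies the input ``k`` lags back (0 = most recent);
    matrices are shared across time and indexed by lag.
    """

    V: Tensor
    W_direct: list = field(default_factory=list)
    window_len: int = 8

    def __post_init__(self):
        if self.window_len < 0:
            raise InvalidParameterError("window_len must be >= 0")


def modified_output(C_t: Tensor, input_history: list, params: ModifiedOutputParams) -> Tensor:
    """Modified LSTM output: linear readout of C_t plus direct input skips.

    ``input_history`` is ordered oldest first; only the most recent
    ``window_len`` entries participate (a longer history is truncated, with
    a log notice).
    """
    history = list(input_history)
    if len(history) > params.window_len:
        logger.info("input history length %d truncated to window %d",
                    len(history), params.window_len)
        history = history[-params.window_len:] if params.window_len > 0 else []
    y = params.V @ C_t
    for lag, x in enumerate(reversed(history)):
        if lag >= len(params.W_direct):
            break
        y = y + params.W_direct[lag] @ x
    return y


def stacked_forward(
    x_seq,
    layers: list,
    keep_prob: float = 1.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    states: list | None = None,
) -> tuple[list, list]:
    """Run a stack of LSTM layers over a sequence.

    Inverted dropout with retention probability ``keep_prob`` is applied to
    each layer's output in training mode (masks drawn per timestep from
    ``rng``); evaluation mode is deterministic (identity).  Returns the top
    layer's outputs and the final per-layer states.
    """
    if not (0.0 < keep_prob <= 1.0):
        raise InvalidParameterError("keep_prob must be in (0, 1]")
    if training and keep_prob < 1.0 and rng is None:
        raise InvalidParameterError("training-mode dropout requires an rng")
    if states is None:
        states = [LSTMState.zeros(w.hidden_size) for w in layers]
    outputs = []
    for x in x_seq:
        h = x if isinstance(x, Tensor) else Tensor(x)
        for li, w in enumerate(layers):
            h, states[li] = lstm_step(h, states[li], w)
            if training and keep_prob < 1.0:
                mask = (rng.random(h.shape) < keep_prob) / keep_prob
                h = h * Tensor(mask)
        outputs.append(h)
    return outputs, states
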