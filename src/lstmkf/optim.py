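"""Adaptive gradient optimizer with an L^p / infinity-norm second moment.

Adam scales each coordinate's step by an exponential moving average of
squared gradients (an L^2 norm).  Generalizing the accumulator to the L^p
norm,

    v_t = beta2^p v_{t-1} + (1 - beta2^p) |g_t|^p,          (finite p)

is numerically unstable for large p, but the limit p -> infinity collapses
to the simple, stable recursion

    v_t = max(beta2 * v_{t-1}, |g_t|),    v_0 = 0,

an exponentially decayed running infinity norm of past gradients (the
AdaMax family).  The infinity-norm accumulator needs no initialization bias
correction; the first moment keeps the standard beta1 exponential average
with bias correction, and the parameter step is

    theta <- theta - alpha * m_hat / (v + eps).

Both the finite-p recursion and its closed-form expansion
``max_i beta2^(t-i) |g_i|`` are exposed so the two routes can be checked
against each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor
from .errors import InvalidParameterError

__all__ = [
    "update_v_inf",
    "expanded_v_inf",
    "update_v_p",
    "AdaMax",
]

logger = logging.getLogger(__name__)


def update_v_inf(v_prev: np.ndarray, g: np.ndarray, beta2: float) -> np.ndarray:
    """One step of the infinity-norm recursion v = max(beta2 * v_prev, |g|)."""
    v_prev = np.asarray(v_prev, dtype=np.float64)
    if np.any(v_prev < 0):
        raise InvalidParameterError("v_prev must be non-negative")
    return np.maximum(beta2 * v_prev, np.abs(np.asarray(g, dtype=np.float64)))


def expanded_v_inf(grads: Sequence[np.ndarray], beta2: float) -> np.ndarray:
    """Closed form of the recursion: v_t = max_i beta2^(t-i) |g_i|.

    The independent oracle for :func:`update_v_inf` — evaluates the decayed
    maximum over the whole gradient history at once.
    """
    grads = [np.asarray(g, dtype=np.float64) for g in grads]
    if len(grads) == 0:
        raise InvalidParameterError("empty gradient sequence")
    t = len(grads)
    stacked = np.stack([beta2 ** (t - 1 - i) * np.abs(g) for i, g in enumerate(grads)])
    return stacked.max(axis=0)


def update_v_p(v_prev: np.ndarray, g: np.ndarray, beta2: float, p: float) -> np.ndarray:
    """Finite-p accumulator v = beta2^p v_prev + (1 - beta2^p) |g|^p.

    The effective per-coordinate scale is ``v ** (1/p)``; as p grows this
    approaches the infinity-norm recursion but overflows for large p, which
    is surfaced as a range error rather than silently producing inf.
    """
    if p < 1 or not np.isfinite(p):
        raise InvalidParameterError("p must be a finite number >= 1")
    v_prev = np.asarray(v_prev, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("error", RuntimeWarning)
        try:
            bp = beta2**p
            v = bp * v_prev + (1.0 - bp) * np.abs(np.asarray(g, dtype=np.float64)) ** p
        except (RuntimeWarning, OverflowError) as e:
            raise FloatingPointError(f"L^p accumulator overflow at p={p}: {e}") from None
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"L^p accumulator overflow at p={p}")
    return v


@dataclass
class AdaMax:
    """Infinity-norm Adam over a named parameter collection.

    Parameters are :class:`~lstmkf.autodiff.Tensor` leaves (gradients read
    from ``.grad``) or the step can be driven explicitly through
    :meth:`apply_update` with raw arrays.  Non-finite gradients skip the
    affected parameter's update for that step (logged), leaving its state
    untouched.
    """

    alpha: float = 2e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise InvalidParameterError("beta1, beta2 must lie in [0, 1)")
        if self.alpha <= 0:
            raise InvalidParameterError("alpha must be positive")

    def step(self, params: Mapping[str, Tensor], lr: float | None = None) -> None:
        """Read ``.grad`` from each parameter tensor and update it in place."""
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in params.items()}
        new = self.apply_update({k: p.data for k, p in params.items()}, grads, lr=lr)
        for k, p in params.items():
            p.data = new[k]

    def apply_update(self, params: Mapping[str, np.ndarray],
                     grads: Mapping[str, np.ndarray],
                     lr: float | None = None) -> dict[str, np.ndarray]:
        """One optimizer step on raw arrays; returns the updated parameters."""
        self.t += 1
        alpha = self.alpha if lr is None else lr
        bc = 1.0 - self.beta1**self.t  # first-moment bias correction
        out = {}
        for k, theta in params.items():
            g = np.asarray(grads[k], dtype=np.float64)
            if k not in self.m:
                self.m[k] = np.zeros_like(theta, dtype=np.float64)
                self.v[k] = np.zeros_like(theta, dtype=np.float64)
            if not np.all(np.isfinite(g)):
                logger.warning("non-finite gradient for %s at step %d; skipping", k, self.t)
                out[k] = np.asarray(theta, dtype=np.float64)
                continue
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = update_v_inf(self.v[k], g, self.beta2)
            out[k] = theta - alpha * (self.m[k] / bc) / (self.v[k] + self.eps)
        return out

    # -- checkpointing ---------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "alpha": self.alpha,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "eps": self.eps,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.alpha = float(state["alpha"])
        self.beta1 = float(state["beta1"])
        self.beta2 = float(state["beta2"])
        self.eps = float(state["eps"])
        self.m = {k: np.array(v, dtype=np.float64) for k, v in state["m"].items()}
        self.v = {k: np.array(v, dtype=np.float64) for k, v in state["v"].items()}
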