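"""Classical Kalman filtering and smoothing baselines.

The linear-Gaussian state-space model is

    y_t = A y_{t-1} + w,   w ~ N(0, Q)
    z_t = H y_t + v,       v ~ N(0, R)

with predict step ``y' = f(y), P' = F P F^T + Q`` and update step
``K = P' H^T (H P' H^T + R)^-1`` (here written for general H; the learned
filter uses H = I).  Alongside the filter live the two standard kinematic
motion models (constant velocity, constant acceleration, discretized with
the white-noise-acceleration process covariance) and an exponential moving
average smoother — the comparison suite the learned filter is benchmarked
against, and the numeric predict/update core it reuses.

Missing measurements (occlusion / dropped detections) are represented
explicitly as ``None`` / NaN rows; the filter then runs prediction only
for that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DimensionError, InvalidParameterError

__all__ = [
    "LinearGaussianModel",
    "Belief",
    "kf_predict",
    "kf_update",
    "constant_velocity_model",
    "constant_acceleration_model",
    "ema_smoother",
    "run_filter",
]


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-9) -> None:
    if np.max(np.abs(M - M.T)) > 1e-9:
        raise InvalidParameterError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(M)) < -tol:
        raise InvalidParameterError(f"{name} must be positive semidefinite")


@dataclass
class LinearGaussianModel:
    """Transition A, observation H, and noise covariances Q (process), R (measurement)."""

    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=np.float64))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=np.float64))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=np.float64))
        _check_psd(self.Q, "Q")
        _check_psd(self.R, "R")

    @property
    def dim(self) -> int:
        return self.A.shape[0]


@dataclass
class Belief:
    """Filter state at one timestep: mean ``y`` and covariance ``P``."""

    y: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=np.float64))
        if self.P.shape != (self.y.size, self.y.size):
            raise DimensionError("P shape does not match state dimension")


def kf_predict(
    belief: Belief,
    f: Callable[[np.ndarray], np.ndarray],
    F: np.ndarray,
    Q: np.ndarray,
) -> Belief:
    """Prediction step: y' = f(y), P' = F P F^T + Q.

    ``f`` may be nonlinear; ``F`` is its Jacobian at the current mean
    (extended-KF linearization; for a linear model pass ``f = A @ .`` and
    ``F = A``).
    """
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    d = belief.y.size
    if F.shape != (d, d) or Q.shape != (d, d):
        raise DimensionError("F and Q must be d x d")
    y_pred = np.atleast_1d(np.asarray(f(belief.y), dtype=np.float64))
    P_pred = F @ belief.P @ F.T + Q
    return Belief(y_pred, 0.5 * (P_pred + P_pred.T))


def kf_update(belief_pred: Belief, z: np.ndarray, R: np.ndarray,
              H: np.ndarray | None = None) -> Belief:
    """Measurement update: K = P'H^T(HP'H^T+R)^-1; y = y' + K(z - Hy'); P = (I-KH)P'.

    With the default H = I this is exactly the gain/update used by the
    learned filter.  The posterior covariance is symmetrized to control
    floating-point drift.
    """
    y_pred, P_pred = belief_pred.y, belief_pred.P
    d = y_pred.size
    z = np.atleast_1d(np.asarray(z, dtype=np.float64))
    R = np.atleast_2d(np.asarray(R, dtype=np.float64))
    if H is None:
        H = np.eye(d)
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    S = H @ P_pred @ H.T + R
    K = np.linalg.solve(S.T, H @ P_pred.T).T  # P' H^T S^-1
    y_post = y_pred + K @ (z - H @ y_pred)
    P_post = (np.eye(d) - K @ H) @ P_pred
    return Belief(y_post, 0.5 * (P_post + P_post.T))


def _wna_Q(dt: float, q: float, order: int) -> np.ndarray:
    """White-noise-acceleration process covariance block for one axis.

    ``order`` = 2 (position, velocity) or 3 (position, velocity,
    acceleration); ``q`` is the noise spectral density.
    """
    if order == 2:
        return q * np.array([[dt**3 / 3.0, dt**2 / 2.0], [dt**2 / 2.0, dt]])
    return q * np.array(
        [
            [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
            [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
            [dt**3 / 6.0, dt**2 / 2.0, dt],
        ]
    )


def _kinematic_model(space_dim: int, dt: float, q: float, r: float, order: int
                     ) -> LinearGaussianModel:
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if q < 0 or r < 0:
        raise InvalidParameterError("q and r must be non-negative")
    if order == 2:
        A1 = np.array([[1.0, dt], [0.0, 1.0]])
    else:
        A1 = np.array([[1.0, dt, dt**2 / 2.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    A = np.kron(np.eye(space_dim), A1)
    Q = np.kron(np.eye(space_dim), _wna_Q(dt, q, order))
    # measurement observes position only
    H1 = np.zeros((1, order))
    H1[0, 0] = 1.0
    H = np.kron(np.eye(space_dim), H1)
    R = r * np.eye(space_dim)
    return LinearGaussianModel(A, H, Q, R)


def constant_velocity_model(space_dim: int = 3, dt: float = 1.0,
                            q: float = 1.0, r: float = 1.0) -> LinearGaussianModel:
    """[position; velocity] kinematics; measurements observe position only."""
    return _kinematic_model(space_dim, dt, q, r, order=2)


def constant_acceleration_model(space_dim: int = 3, dt: float = 1.0,
                                q: float = 1.0, r: float = 1.0) -> LinearGaussianModel:
    """[position; velocity; acceleration] kinematics; position-only measurements."""
    return _kinematic_model(space_dim, dt, q, r, order=3)


def ema_smoother(z_seq: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average: ŷ_t = α z_t + (1-α) ŷ_{t-1}, ŷ_0 = z_0.

    Rows of ``z_seq`` that are entirely NaN (dropout frames) hold the
    previous smoothed value.
    """
    if not (0.0 < alpha <= 1.0):
        raise InvalidParameterError("alpha must be in (0, 1]")
    z_seq = np.atleast_1d(np.asarray(z_seq, dtype=np.float64))
    out = np.empty_like(z_seq, dtype=np.float64)
    prev = None
    for t in range(len(z_seq)):
        z = z_seq[t]
        missing = np.all(np.isnan(np.atleast_1d(z)))
        if prev is None:
            if missing:
                raise InvalidParameterError("first frame must have a measurement")
            prev = np.array(z, dtype=np.float64)
        elif not missing:
            prev = alpha * z + (1.0 - alpha) * prev
        out[t] = prev
    return out


@dataclass
class FilterResult:
    """Per-frame posterior means/covariances plus predicted (prior) means."""

    means: np.ndarray
    covariances: np.ndarray
    predicted_means: np.ndarray
    updated: np.ndarray = field(default=None)  # bool per frame


def run_filter(model: LinearGaussianModel, z_seq: Sequence,
               init: Belief | None = None) -> FilterResult:
    """Filter a measurement sequence, skipping updates on gap frames.

    ``z_seq`` is a sequence of measurement vectors; ``None`` or an all-NaN
    row marks a gap (prediction-only frame).  The first frame must carry a
    measurement unless ``init`` supplies the starting belief: the observed
    state blocks are initialized from z_0 with variance R, the unobserved
    (velocity/acceleration) blocks start at zero with a large variance.
    """
    z_list = list(z_seq)
    if len(z_list) == 0:
        raise InvalidParameterError("empty measurement sequence")
    d = model.dim
    m = model.H.shape[0]

    def _gap(z) -> bool:
        return z is None or np.all(np.isnan(np.atleast_1d(np.asarray(z, dtype=np.float64))))

    if init is None:
        if _gap(z_list[0]):
            raise InvalidParameterError("first frame must have a measurement")
        z0 = np.atleast_1d(np.asarray(z_list[0], dtype=np.float64))
        y0 = model.H.T @ z0  # place observed components, zero elsewhere
        P0 = model.H.T @ model.R @ model.H + 1e4 * (np.eye(d) - model.H.T @ model.H)
        belief = Belief(y0, P0)
        start = 1
    else:
        belief = init
        start = 0

    means = np.empty((len(z_list), d))
    covs = np.empty((len(z_list), d, d))
    pred_means = np.empty((len(z_list), d))
    updated = np.zeros(len(z_list), dtype=bool)

    if init is None:
        means[0] = belief.y
        covs[0] = belief.P
        pred_means[0] = belief.y
        updated[0] = True

    A = model.A
    for t in range(start, len(z_list)):
        belief = kf_predict(belief, lambda y: A @ y, A, model.Q)
        pred_means[t] = belief.y
        z = z_list[t]
        if not _gap(z):
            belief = kf_update(belief, np.atleast_1d(np.asarray(z, dtype=np.float64))[:m],
                               model.R, model.H)
            updated[t] = True
        means[t] = belief.y
        covs[t] = belief.P
    return FilterResult(means, covs, pred_means, updated)
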