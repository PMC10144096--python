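"""End-to-end training loops for the learned filter and the plain-LSTM baseline.

Training uses truncated backpropagation through time (TBPTT): each
sequence is cut into fixed-length windows; the recurrent state *and* the
filter belief are carried across window boundaries but the tape is cut, so
gradients flow only within a window.  One optimizer step is taken per
window (gradients accumulated over ``batch_size`` sequences advancing in
lockstep).  The learning rate follows a geometric schedule — ``lr0`` for
the first epoch, decayed by a fixed factor each epoch from the second —
and gradients are globally norm-clipped for stability.

The reference protocol for the learned filter trains at lr0 = 2e-5 with
decay 0.95 and 100-step windows; the plain single-layer LSTM baseline
(16 hidden units, mapping the measurement directly to a state estimate)
trains at 5e-4, batch size 2, 10-step windows for 120 epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cells import LSTMState, init_lstm_weights, lstm_step
from .errors import InvalidParameterError
from .model import LSTMKF, sequence_loss
from .optim import AdaMax

__all__ = [
    "TrainConfig",
    "STD_LSTM_TRAIN_CONFIG",
    "lr_schedule",
    "tbptt_train",
    "StdLSTM",
    "train_std_lstm_baseline",
    "clip_gradients",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Schedule and loop constants for TBPTT training."""

    lr0: float = 2e-5
    decay: float = 0.95
    decay_start_epoch: int = 2
    tbptt_window: int = 100
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0
    clip_norm: float = 10.0
    teacher_forcing: bool = False
    lam: float = 1.0
    patience: int | None = None  # early stopping on the validation metric
    val_metric: str = "loss"  # "loss" or "posterior_rmse"
    restore_best: bool = True  # keep the best-validation weights

    def __post_init__(self):
        if self.lr0 <= 0:
            raise InvalidParameterError("lr0 must be positive")
        if not (0.0 < self.decay <= 1.0):
            raise InvalidParameterError("decay must be in (0, 1]")
        if self.tbptt_window < 1:
            raise InvalidParameterError("tbptt_window must be >= 1")


#: The baseline protocol: 16 hidden units, batch 2, lr 5e-4, 120 epochs, 10-step windows.
STD_LSTM_TRAIN_CONFIG = TrainConfig(lr0=5e-4, tbptt_window=10, batch_size=2,
                                    epochs=120, lam=0.0)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """lr0 for the first epoch; lr0 * decay^(epoch-1) from the decay start."""
    if epoch < 1:
        raise InvalidParameterError("epoch counts from 1")
    exponent = max(epoch - cfg.decay_start_epoch + 1, 0)
    return cfg.lr0 * cfg.decay**exponent


def clip_gradients(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale  # no in-place: buffers may be shared
    return norm


def _as_pairs(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize a dataset to (truth, measurements) float arrays with NaN gaps."""
    pairs = []
    for item in dataset:
        if isinstance(item, tuple):
            truth, z = item
        else:  # SimulatedSequence-style object
            truth, z = item.positions, item.measurements
        pairs.append((np.asarray(truth, dtype=np.float64),
                      np.asarray(z, dtype=np.float64)))
    if not pairs:
        raise InvalidParameterError("dataset is empty")
    return pairs


def _gap(z_row: np.ndarray) -> bool:
    return bool(np.all(np.isnan(z_row)))


def _detach_state(state):
    """TBPTT cut for either filter-state objects or (lstm, tensor) tuples."""
    if hasattr(state, "detach"):
        return state.detach()
    return tuple(x.detach() for x in state)


def evaluate_posterior_rmse(model, dataset) -> float:
    """RMSE of the posterior estimates over a dataset (no gradients)."""
    total, count = 0.0, 0
    with ad.no_grad():
        for truth, z in _as_pairs(dataset):
            est = model.run(list(z))["means"] if hasattr(model, "run") else None
            if est is None:  # pragma: no cover - all filters expose run()
                raise InvalidParameterError("model must expose run()")
            total += float(((truth[1:] - est[1:]) ** 2).sum())
            count += (len(truth) - 1) * truth.shape[1]
    return float(np.sqrt(total / count))


def evaluate_loss(model, dataset, lam: float = 1.0) -> float:
    """Mean sequence loss of a model over a dataset (no gradients)."""
    total, count = 0.0, 0
    squared = getattr(getattr(model, "cfg", None), "squared_loss", False)
    with ad.no_grad():
        for truth, z in _as_pairs(dataset):
            state = model.init_state(z[0])
            y_hats, y_primes, y_trues = [], [], []
            for t in range(1, len(z)):
                z_t = None if _gap(z[t]) else z[t]
                y_hat, state, extras = model.step(state, z_t)
                y_hats.append(y_hat)
                y_primes.append(extras["y_prime"])
                y_trues.append(truth[t])
            total += sequence_loss(y_trues, y_hats, y_primes, lam=lam,
                                   squared=squared).item()
            count += 1
    return total / count


def tbptt_train(model, dataset, cfg: TrainConfig,
                optimizer: AdaMax | None = None,
                rng: np.random.Generator | None = None,
                val_dataset=None,
                start_epoch: int = 1) -> list[float]:
    """Train ``model`` in place; returns the per-epoch mean training loss.

    ``model`` is any object with the filter interface (``init_state``,
    ``step``, ``parameters``, ``zero_grad``) — the learned Kalman filter or
    the plain LSTM baseline.  Sequences advance in lockstep groups of
    ``batch_size``; each window's summed loss produces one optimizer step,
    after which every sequence's state is detached (the TBPTT cut).  With
    ``patience`` set and a validation set given, training stops early when
    the validation loss has not improved for that many epochs.
    """
    pairs = _as_pairs(dataset)
    squared = getattr(getattr(model, "cfg", None), "squared_loss", False)
    if optimizer is None:
        optimizer = AdaMax(alpha=cfg.lr0)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    min_T = min(len(z) for _, z in pairs)
    if cfg.tbptt_window > min_T - 1:
        logger.info("tbptt window %d exceeds shortest sequence (%d frames); "
                    "tail windows will be short", cfg.tbptt_window, min_T)

    history: list[float] = []
    best_val, best_bad = np.inf, 0
    best_params: dict[str, np.ndarray] | None = None
    for epoch in range(start_epoch, start_epoch + cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        epoch_loss, n_windows = 0.0, 0
        for g0 in range(0, len(pairs), cfg.batch_size):
            group = pairs[g0:g0 + cfg.batch_size]
            states = [model.init_state(z[0]) for _, z in group]
            T = min(len(z) for _, z in group)
            for w0 in range(1, T, cfg.tbptt_window):
                w1 = min(w0 + cfg.tbptt_window, T)
                model.zero_grad()
                window_loss = Tensor(0.0)
                for si, (truth, z) in enumerate(group):
                    state = states[si]
                    y_hats, y_primes, y_trues = [], [], []
                    for t in range(w0, w1):
                        z_t = None if _gap(z[t]) else z[t]
                        y_in = Tensor(truth[t - 1]) if cfg.teacher_forcing else None
                        y_hat, state, extras = model.step(
                            state, z_t, training=True, rng=rng, y_input=y_in)
                        y_hats.append(y_hat)
                        y_primes.append(extras["y_prime"])
                        y_trues.append(truth[t])
                    states[si] = state
                    window_loss = window_loss + sequence_loss(
                        y_trues, y_hats, y_primes, lam=cfg.lam,
                        squared=squared)
                window_loss = window_loss / float(len(group))
                window_loss.backward()
                clip_gradients(params, cfg.clip_norm)
                optimizer.step(params, lr=lr)
                states = [_detach_state(s) for s in states]
                epoch_loss += window_loss.item() * (w1 - w0)
                n_windows += w1 - w0
        mean_loss = epoch_loss / n_windows
        history.append(mean_loss)
        logger.info("epoch %d lr %.3g loss %.6g", epoch, lr, mean_loss)
        if not np.isfinite(mean_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        if val_dataset is not None:
            if cfg.val_metric == "posterior_rmse":
                val = evaluate_posterior_rmse(model, val_dataset)
            else:
                val = evaluate_loss(model, val_dataset, lam=cfg.lam)
            logger.info("epoch %d validation %s %.6g", epoch, cfg.val_metric, val)
            if val < best_val - 1e-9:
                best_val, best_bad = val, 0
                if cfg.restore_best:
                    best_params = {k: p.data.copy() for k, p in params.items()}
            else:
                best_bad += 1
                if cfg.patience is not None and best_bad >= cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_params is not None:
        for k, p in params.items():
            p.data = best_params[k]
    return history


class StdLSTM:
    """Plain single-layer LSTM regressor z_t -> y_t (the non-filter baseline).

    Exposes the same stepping interface as the learned filter so the same
    TBPTT loop trains both.  Gap frames reuse the last seen measurement as
    input.  With scarce training data this architecture has to memorize
    trajectories rather than learn a motion model — the failure mode the
    comparison harness exhibits.
    """

    def __init__(self, state_dim: int = 3, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.state_dim = state_dim
        self.hidden = hidden
        self.lstm = init_lstm_weights(state_dim, hidden, rng)
        bound = 1.0 / np.sqrt(hidden)
        self.W_out = Tensor(rng.uniform(-bound, bound, (state_dim, hidden)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(state_dim), requires_grad=True)
        self.input_mean = np.zeros(state_dim)
        self.input_scale = np.ones(state_dim)
        self.output_mean = np.zeros(state_dim)
        self.output_scale = np.ones(state_dim)

    def parameters(self) -> dict[str, Tensor]:
        params = self.lstm.tensors("lstm")
        params["out.W"] = self.W_out
        params["out.b"] = self.b_out
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def fit_input_scaler(self, sequences) -> None:
        stacked = np.concatenate([np.asarray(s, dtype=np.float64).reshape(-1, self.state_dim)
                                  for s in sequences])
        stacked = stacked[np.all(np.isfinite(stacked), axis=1)]
        self.input_mean = self.output_mean = stacked.mean(axis=0)
        self.input_scale = self.output_scale = np.maximum(stacked.std(axis=0), 1e-6)

    def init_state(self, z0):
        return (LSTMState.zeros(self.hidden),
                Tensor(np.asarray(z0, dtype=np.float64).copy()))

    def step(self, state, z, training: bool = False, rng=None, y_input=None):
        lstm_state, last_z = state
        z_in = last_z if z is None else Tensor(np.asarray(z, dtype=np.float64))
        x = (z_in - Tensor(self.input_mean)) * Tensor(1.0 / self.input_scale)
        h, lstm_state = lstm_step(x, lstm_state, self.lstm)
        y_hat = (self.W_out @ h + self.b_out) * Tensor(self.output_scale) \
            + Tensor(self.output_mean)
        return y_hat, (lstm_state, z_in), {"y_prime": y_hat}

    def run(self, z_seq) -> np.ndarray:
        z_seq = np.asarray(z_seq, dtype=np.float64)
        state = self.init_state(z_seq[0])
        out = np.empty_like(z_seq)
        out[0] = z_seq[0]
        with ad.no_grad():
            for t in range(1, len(z_seq)):
                z_t = None if _gap(z_seq[t]) else z_seq[t]
                y_hat, state, _ = self.step(state, z_t)
                out[t] = y_hat.data
        return out

    @staticmethod
    def _detach_state(state):
        return (state[0].detach(), state[1].detach())


def train_std_lstm_baseline(dataset, cfg: TrainConfig | None = None,
                            state_dim: int = 3, hidden: int = 16,
                            seed: int = 0) -> tuple[StdLSTM, list[float]]:
    """Train the plain LSTM baseline at its reference protocol (or ``cfg``)."""
    cfg = cfg or STD_LSTM_TRAIN_CONFIG
    model = StdLSTM(state_dim=state_dim, hidden=hidden, seed=seed)
    model.fit_input_scaler([t for t, _ in _as_pairs(dataset)])
    optimizer = AdaMax(alpha=cfg.lr0)
    history = tbptt_train(model, dataset, cfg, optimizer=optimizer,
                          rng=np.random.default_rng(seed))
    return model, history


# -- checkpointing -------------------------------------------------------

def save_checkpoint(path: str, model: LSTMKF, optimizer: AdaMax,
                    rng: np.random.Generator, epoch: int,
                    history: list[float]) -> None:
    """Serialize model + optimizer + rng state for exact resume."""
    import pickle  # rng bit-generator state is a plain dict; npz can't hold it

    model.save(str(path) + ".model")
    state = {
        "optimizer": optimizer.state_dict(),
        "rng_state": rng.bit_generator.state,
        "epoch": epoch,
        "history": list(history),
    }
    with open(str(path) + ".state.pkl", "wb") as fh:
        pickle.dump(state, fh)


def load_checkpoint(path: str) -> tuple[LSTMKF, AdaMax, np.random.Generator,
                                        int, list[float]]:
    import pickle

    model = LSTMKF.load(str(path) + ".model")
    with open(str(path) + ".state.pkl", "rb") as fh:
        state = pickle.load(fh)
    optimizer = AdaMax()
    optimizer.load_state_dict(state["optimizer"])
    rng = np.random.default_rng()
    rng.bit_generator.state = state["rng_state"]
    return model, optimizer, rng, state["epoch"], state["history"]
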