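"""Minimal reverse-mode automatic differentiation on numpy arrays.

The differentiable Kalman filter needs gradients of a scalar loss with
respect to every network parameter, propagated *through* the filter's
prediction and update equations (matrix products, an inverse, gate
nonlinearities).  This module provides the small tape-based engine used for
that: a :class:`Tensor` wraps a float64 ``ndarray``, records its parents and
a backward closure, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.

Only the primitives the tracking models need are implemented (elementwise
arithmetic with numpy broadcasting, matmul, sigmoid/tanh/relu/exp/log/sqrt,
sum/mean, concatenation, slicing, transpose, matrix inverse, a safe
Euclidean norm, and a clip with pass-through gradient).  Everything is
float64; graphs are built eagerly and freed with the tensors that own them.
When no input requires a gradient the ops skip tape construction entirely,
so inference pays almost nothing for running on the same code path.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "sqrt",
    "absval",
    "clip",
    "inv",
    "l2norm",
    "scale_rows",
    "sigmoid_deriv",
    "tanh_deriv",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference fast path)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node of the autodiff tape: float64 data plus gradient plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self._grad_owned = False

    # -- construction helpers -------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        """Constant leaf with the same values (gradient flow stops here)."""
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, g) -> None:
        # First contribution keeps a reference (no copy); a second one forces
        # a fresh buffer so shared gradient arrays are never mutated.
        if not isinstance(g, np.ndarray) or g.dtype != np.float64:
            g = np.asarray(g, dtype=np.float64)
        if g.shape != self.data.shape:
            g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- backward pass ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this node into every leaf.

        ``grad`` seeds the output gradient and defaults to ones (a scalar
        loss seeds 1.0).  Iterative topological order; safe for the long
        tapes produced by unrolled sequence models.
        """
        if not self.requires_grad:
            raise ValueError("called backward() on a non-differentiable tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_req = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data + other.data, out_req, (self, other) if out_req else ())
        if out_req:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g)
                if b.requires_grad:
                    b._accumulate(g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        req = _GRAD_ENABLED and self.requires_grad
        out = Tensor(-self.data, req, (self,) if req else ())
        if req:
            out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_req = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data * other.data, out_req, (self, other) if out_req else ())
        if out_req:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g * b.data)
                if b.requires_grad:
                    b._accumulate(g * a.data)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_req = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data / other.data, out_req, (self, other) if out_req else ())
        if out_req:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g / b.data)
                if b.requires_grad:
                    b._accumulate(-g * a.data / (b.data * b.data))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out_req = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data @ other.data, out_req, (self, other) if out_req else ())
        if out_req:
            a_nd, b_nd = self.data.ndim, other.data.ndim

            def _bw(g, a=self, b=other):
                g = np.asarray(g, dtype=np.float64)
                if a_nd == 2 and b_nd == 2:
                    if a.requires_grad:
                        a._accumulate(g @ b.data.T)
                    if b.requires_grad:
                        b._accumulate(a.data.T @ g)
                elif a_nd == 2 and b_nd == 1:
                    if a.requires_grad:
                        a._accumulate(g[:, None] * b.data[None, :])
                    if b.requires_grad:
                        b._accumulate(a.data.T @ g)
                elif a_nd == 1 and b_nd == 2:
                    if a.requires_grad:
                        a._accumulate(g @ b.data.T)
                    if b.requires_grad:
                        b._accumulate(a.data[:, None] * g[None, :])
                elif a_nd == 1 and b_nd == 1:  # dot product, g scalar
                    if a.requires_grad:
                        a._accumulate(g * b.data)
                    if b.requires_grad:
                        b._accumulate(g * a.data)
                else:  # pragma: no cover - higher-rank matmul unused
                    raise NotImplementedError("matmul backward for ndim > 2")
            out._backward = _bw
        return out

    # -- reductions and shape ops ---------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        req = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     req, (self,) if req else ())
        if req:
            def _bw(g, a=self, ax=axis, kd=keepdims):
                g = np.asarray(g, dtype=np.float64)
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / float(n)

    def reshape(self, *shape):
        req = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.reshape(*shape), req, (self,) if req else ())
        if req:
            out._backward = lambda g, a=self: a._accumulate(
                np.asarray(g).reshape(a.data.shape))
        return out

    @property
    def T(self):
        req = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.T, req, (self,) if req else ())
        if req:
            out._backward = lambda g, a=self: a._accumulate(np.asarray(g).T)
        return out

    def __getitem__(self, idx):
        req = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data[idx], req, (self,) if req else ())
        if req:
            # basic (slice/int) indexing never repeats elements, so plain
            # assignment scatters the gradient; fancy indexing needs add.at
            basic = isinstance(idx, (slice, int)) or (
                isinstance(idx, tuple)
                and all(isinstance(e, (slice, int)) for e in idx))

            def _bw(g, a=self, i=idx, simple=basic):
                full = np.zeros_like(a.data)
                if simple:
                    full[i] = g
                else:
                    np.add.at(full, i, np.asarray(g, dtype=np.float64))
                a._accumulate(full)
            out._backward = _bw
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x: Tensor, value: np.ndarray, vjp: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    req = _GRAD_ENABLED and x.requires_grad
    out = Tensor(value, req, (x,) if req else ())
    if req:
        out._backward = lambda g, a=x: a._accumulate(vjp(np.asarray(g, dtype=np.float64)))
    return out


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    x = as_tensor(x)
    s = expit(x.data)
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    return _unary(x, t, lambda g: g * (1.0 - t * t))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _unary(x, np.where(mask, x.data, 0.0), lambda g: g * mask)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    return _unary(x, e, lambda g: g * e)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.log(x.data), lambda g: g / x.data)


def absval(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sign(x.data)
    return _unary(x, np.abs(x.data), lambda g: g * s)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    r = np.sqrt(x.data)
    return _unary(x, r, lambda g: g * 0.5 / r)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the open range."""
    x = as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)
    return _unary(x, np.clip(x.data, lo, hi), lambda g: g * mask)


def inv(a: Tensor) -> Tensor:
    """Matrix inverse with the standard pullback d(A^-1) = -A^-1 dA A^-1."""
    a = as_tensor(a)
    ainv = np.linalg.inv(a.data)
    return _unary(a, ainv, lambda g: -ainv.T @ np.asarray(g, dtype=np.float64) @ ainv.T)


def l2norm(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Euclidean norm with a bounded subgradient at the origin."""
    x = as_tensor(x)
    n = float(np.sqrt(np.sum(x.data * x.data)))
    return _unary(x, np.asarray(n), lambda g: g * x.data / max(n, eps))


def scale_rows(v: Tensor, M: Tensor) -> Tensor:
    """diag(v) @ M for a vector v and matrix M (fused row scaling)."""
    v = as_tensor(v)
    M = as_tensor(M)
    out_req = _GRAD_ENABLED and (v.requires_grad or M.requires_grad)
    out = Tensor(v.data[:, None] * M.data, out_req, (v, M) if out_req else ())
    if out_req:
        def _bw(g, a=v, b=M):
            g = np.asarray(g, dtype=np.float64)
            if a.requires_grad:
                a._accumulate((g * b.data).sum(axis=1))
            if b.requires_grad:
                b._accumulate(a.data[:, None] * g)
        out._backward = _bw
    return out


def sigmoid_deriv(s: Tensor) -> Tensor:
    """s * (1 - s), the logistic derivative expressed in the gate value s."""
    s = as_tensor(s)
    val = s.data * (1.0 - s.data)
    return _unary(s, val, lambda g: g * (1.0 - 2.0 * s.data))


def tanh_deriv(t: Tensor) -> Tensor:
    """1 - t^2, the tanh derivative expressed in the activation value t."""
    t = as_tensor(t)
    return _unary(t, 1.0 - t.data * t.data, lambda g: g * (-2.0 * t.data))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_req = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 out_req, tuple(tensors) if out_req else ())
    if out_req:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g, ts=tensors):
            pieces = np.split(np.asarray(g, dtype=np.float64), splits, axis=axis)
            for t, piece in zip(ts, pieces):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _bw
    return out
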