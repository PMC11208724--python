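"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients into every reachable leaf with
``requires_grad=True``.

The op set is deliberately small: dense linear algebra, the elementwise
nonlinearities used by gated recurrent units and attention, row gathering and
segment reductions for batched molecular graphs, and the simplex/log ops the
reconstruction losses need. Shapes are restricted to what the package uses
(scalars, vectors, 2-D matrices); broadcasting follows NumPy rules and is
undone on the backward pass by summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that NumPy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------------

    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g, out):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- elementwise nonlinearities -------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g, out: (g * out.data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def clamp_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        return Tensor._from_op(np.maximum(self.data, lo), (self,), lambda g, out: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g, out: (g * (1 - out.data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,), lambda g, out: (g * out.data * (1 - out.data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g, out: (g * mask,))

    def leaky_relu(self, alpha: float = 0.01):
        slope = np.where(self.data > 0, 1.0, alpha)
        return Tensor._from_op(self.data * slope, (self,), lambda g, out: (g * slope,))

    def elu(self, alpha: float = 1.0):
        out_data = np.where(self.data > 0, self.data, alpha * (np.exp(self.data) - 1.0))
        deriv = np.where(self.data > 0, 1.0, out_data + alpha)
        return Tensor._from_op(out_data, (self,), lambda g, out: (g * deriv,))

    def cols(self, a: int, b: int):
        """Column slice ``x[:, a:b]`` of a 2-D tensor."""

        def backward(g, out):
            gx = np.zeros_like(self.data)
            gx[:, a:b] = g
            return (gx,)

        return Tensor._from_op(self.data[:, a:b], (self,), backward)

    def softmax_rows(self):
        """Row-wise softmax of a 2-D tensor."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=1, keepdims=True)

        def backward(g, out):
            s = out.data
            return (s * (g - (g * s).sum(axis=1, keepdims=True)),)

        return Tensor._from_op(out_data, (self,), backward)

    # ---- autodiff driver -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative postorder: molecules are small but tapes are long
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves whose backward is None already handled; also store for self if leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- structural ops ------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """``x[idx]`` along axis 0; scatter-add on the way back."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g, out):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return Tensor._from_op(x.data[idx], (x,), backward)


def segment_sum(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Sum rows of `x` into `n_seg` buckets given per-row segment ids."""
    x = as_tensor(x)
    seg = np.asarray(seg, dtype=np.intp)
    out_data = np.zeros((n_seg,) + x.data.shape[1:])
    np.add.at(out_data, seg, x.data)

    def backward(g, out):
        return (g[seg],)

    return Tensor._from_op(out_data, (x,), backward)


def segment_softmax(scores: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of a column vector of scores within each segment.

    Rows sharing a segment id form one softmax; every segment's entries sum
    to 1. The per-segment max is treated as a constant shift (standard
    log-sum-exp stabilization).
    """
    scores = as_tensor(scores)
    seg = np.asarray(seg, dtype=np.intp)
    flat = scores.data.reshape(-1)
    seg_max = np.full(n_seg, -np.inf)
    np.maximum.at(seg_max, seg, flat)
    shift = Tensor(seg_max[seg].reshape(scores.shape))
    e = (scores - shift).exp()
    denom = gather_rows(segment_sum(e, seg, n_seg), seg)
    return e / denom
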