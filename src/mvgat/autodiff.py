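"""Minimal reverse-mode automatic differentiation on numpy arrays.

The attention network in this package is small (a few thousand parameters)
and trained full-batch, so a compact tape-based engine over dense numpy
arrays is sufficient.  Only the operations the model needs are implemented:
broadcast arithmetic, matmul, the activations used by graph attention
(leaky ReLU, ELU), exp/log, row gathering and segment sums (the sparse
neighbourhood primitives), concatenation and reductions.

Gradients for broadcast operations are reduced back to the operand shape
with :func:`_unbroadcast`.  All gradient rules are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "stack_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape machinery to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones, scalars only)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(np.outer(g, other.data) if self.data.ndim == 2 else g * other.data)
                else:
                    self._accumulate(np.atleast_2d(g) @ other.data.T if self.data.ndim == 2 else g @ other.data.T)
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g) if other.data.ndim == 2 else g * self.data)
                else:
                    other._accumulate(self.data.T @ np.atleast_2d(g) if other.data.ndim == 2 else self.data.T @ g)

        out._backward = backward
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = backward
        return out

    def elu(self, alpha: float = 1.0):
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(self.data > 0, self.data, expm), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, expm + alpha))

        out._backward = backward
        return out

    def sigmoid(self):
        # numerically stable two-branch logistic
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )
        out = Tensor(s, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; the gradient passes straight through inside [lo, hi]."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accumulate(g * inside)

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                g_ = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g_, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out


# ------------------------------------------------------------------ functions
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows (axis 0) of `t` by an integer index array."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], _parents=(t,))

    def backward(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = backward
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    shape = (num_segments,) + t.data.shape[1:]
    acc = np.zeros(shape, dtype=np.float64)
    np.add.at(acc, segment_ids, t.data)
    out = Tensor(acc, _parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    out._backward = backward
    return out


def stack_mean(tensors: list[Tensor]) -> Tensor:
    """Elementwise mean of same-shaped tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out * (1.0 / len(tensors))
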