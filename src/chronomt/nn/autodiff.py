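"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package (wave-wise convolutional encoders, stacked
recurrent blocks, the bidirectional recurrent imputer) are small — a few
thousand parameters, sequences of at most eight time steps — so a compact
tape-based autodiff at matrix-operation granularity is both sufficient and
fast.  Gradients are accumulated into ``Tensor.grad`` by :func:`backward`,
which walks the tape in reverse topological order.

Only the operations the models need are implemented: broadcasting
arithmetic, matrix multiplication, slicing, stacking/concatenation,
reductions, and the usual activations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "relu", "stack", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcasting introduced for `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape.

    Parameters (``requires_grad=True``) and intermediate results share this
    class; constants may be passed as plain arrays or scalars to every
    operation.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # ensure ndarray.__mul__ defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this node; accumulates into ``.grad`` fields."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (recursion depth is unbounded on long tapes)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-grad * self.data / other.data**2, other.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(grad):
            if self.requires_grad:
                g = grad @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ grad
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * np.sign(self.data))

        out._backward = backward
        return out

    # -------------------------------------------------------------- shape ops
    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, grad)
                self._accumulate(full)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.shape))

        out._backward = backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(grad):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accumulate(np.broadcast_to(grad, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ activations
    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * val)

        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad / self.data)

        out._backward = backward
        return out


def sigmoid(x: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = x._make(val, (x,), None)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * val * (1.0 - val))

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    val = np.tanh(x.data)
    out = x._make(val, (x,), None)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * (1.0 - val**2))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x._make(x.data * mask, (x,), None)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * mask)

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (used to reassemble sequences)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(grad):
            pieces = np.split(grad, len(tensors), axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(np.squeeze(g, axis=axis))

        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(grad):
            pieces = np.split(grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = backward
    return out
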