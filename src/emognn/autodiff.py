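"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the primitives the network needs are implemented: broadcasting
elementwise arithmetic, (batched) matmul, relu, stabilized softmax /
log-softmax, reductions, reshape/transpose, and the gradient-reversal
primitive. Every backward rule is exercised by finite-difference checks
in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "cat", "grad_reverse", "nll_loss", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        """Propagate ``grad`` (default: ones, scalar outputs only) to leaves.

        Nodes are processed in reverse topological order so each backward
        rule runs exactly once with the fully summed upstream gradient,
        even on graphs where a tensor feeds several consumers.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)

        # iterative post-order DFS over the requires_grad subgraph
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        buffer: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        prev = Tensor._stage_buffer
        Tensor._stage_buffer = buffer
        try:
            for t in reversed(topo):
                g = buffer.pop(id(t), None)
                if g is None:
                    continue
                if t.grad is None:
                    t.grad = np.zeros_like(t.data)
                t.grad += g
                if t._backward is not None:
                    t._backward(g)
        finally:
            Tensor._stage_buffer = prev

    # ------------------------------------------------------------- op helpers
    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"]) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        out._parents = tuple(p for p in parents if p.requires_grad)
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    _stage_buffer: dict[int, np.ndarray] | None = None

    def _accum(self, g: np.ndarray):
        """Deposit a partial gradient for this tensor.

        Inside a ``backward()`` pass the contribution is staged so the
        node's own rule fires once with the total; outside one (direct use
        of a closure) it falls back to immediate recursive propagation.
        """
        if not self.requires_grad:
            return
        buf = Tensor._stage_buffer
        if buf is not None:
            if id(self) in buf:
                buf[id(self)] = buf[id(self)] + g
            else:
                buf[id(self)] = g
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g
        if self._backward is not None:
            self._backward(g)

    # ------------------------------------------------------------- matmul etc
    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor._make(np.matmul(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def transpose_last(self) -> "Tensor":
        out = Tensor._make(np.swapaxes(self.data, -1, -2), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, -1, -2))
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor._make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- nonlinearity
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor._make(val, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor._make(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor._make(val, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stabilized softmax (max subtraction)."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (self,))

        def backward(g):
            inner = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - inner))

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        logp = shifted - lse
        out = Tensor._make(logp, (self,))

        def backward(g):
            self._accum(g - np.exp(logp) * g.sum(axis=axis, keepdims=True))

        out._backward = backward
        return out


    def __getitem__(self, key) -> "Tensor":
        out = Tensor._make(self.data[key], (self,))

        def backward(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, key, g)
            self._accum(gi)

        out._backward = backward
        return out


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def grad_reverse(x: Tensor, alpha: float) -> Tensor:
    """Identity in the forward pass; multiplies gradients by ``-alpha``."""
    out = Tensor._make(x.data.copy(), (x,))
    out._backward = lambda g: x._accum(-alpha * g)
    return out


def nll_loss(log_probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log likelihood of integer ``targets`` under ``log_probs``."""
    targets = np.asarray(targets, dtype=np.int64)
    n = log_probs.data.shape[0]
    picked = log_probs.data[np.arange(n), targets]
    out = Tensor._make(np.asarray(-picked.mean()), (log_probs,))

    def backward(g):
        gi = np.zeros_like(log_probs.data)
        gi[np.arange(n), targets] = -float(g) / n
        log_probs._accum(gi)

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Softmax cross-entropy from raw logits (mean over the batch)."""
    return nll_loss(logits.log_softmax(axis=-1), targets)
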