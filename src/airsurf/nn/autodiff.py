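"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a recurrent network with attention: a taped
``Tensor`` wrapping an ``ndarray``, a handful of differentiable primitives
with broadcasting-aware gradients, and a topological-order backward pass.
Gradients are validated against central finite differences in the test
suite; the engine is intentionally small rather than general.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters marked ``requires_grad=True`` accumulate gradients in
    ``.grad`` after ``backward()``; constants are recorded on the tape but
    receive no gradient.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._bw = _bw

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth blows up on long tapes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- primitives -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        def bw(g):
            self._accum(g)
            other._accum(g)
        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._bw = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))
        out._bw = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._bw = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        plain = all(isinstance(p, (slice, int)) for p in parts)
        def bw(g):
            full = np.zeros_like(self.data)
            if plain:          # slices never alias, so assignment suffices
                full[idx] = g
            else:              # fancy indices may repeat; accumulate
                np.add.at(full, idx, g)
            self._accum(full)
        out._bw = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._bw = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._bw = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._bw = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._bw = lambda g: self._accum(g * y)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._bw = lambda g: self._accum(g * 0.5 / y)
        return out

    def __pow__(self, p: float):
        y = self.data ** p
        out = Tensor(y, _parents=(self,))
        out._bw = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._bw = bw
    return out
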