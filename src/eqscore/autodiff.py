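"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the equivariant network needs: elementwise
arithmetic with broadcasting, matrix multiplication, reductions, a few
activations, row gathering and segment (scatter-add) sums.  Gradients are
accumulated in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "sigmoid",
    "tanh",
    "relu",
    "silu",
    "softplus",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2,
                                       other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda g: _accum(
            self, g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            _accum(self, g @ other.data.T)
            _accum(other, self.data.T @ g)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _accum(tensor: Tensor, grad: np.ndarray) -> None:
    if tensor.grad is None:
        tensor.grad = np.array(grad, dtype=np.float64)
    else:
        tensor.grad = tensor.grad + grad


# -- structural ops ----------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for tensor, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            _accum(tensor, g[tuple(index)])

    out._backward = backward
    return out


def gather_rows(tensor: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor: out[k] = tensor[index[k]]."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(tensor.data[index], (tensor,))

    def backward(g):
        grad = np.zeros_like(tensor.data)
        np.add.at(grad, index, g)
        _accum(tensor, grad)

    out._backward = backward
    return out


def segment_sum(tensor: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows: out[i] = sum over k with index[k] == i of tensor[k]."""
    index = np.asarray(index, dtype=np.intp)
    data = np.zeros((num_segments,) + tensor.data.shape[1:])
    np.add.at(data, index, tensor.data)
    out = Tensor(data, (tensor,))
    out._backward = lambda g: _accum(tensor, g[index])
    return out


# -- activations -------------------------------------------------------

def sigmoid(tensor: Tensor) -> Tensor:
    tensor = _as_tensor(tensor)
    value = np.where(tensor.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(tensor.data))),
                     np.exp(-np.abs(tensor.data))
                     / (1.0 + np.exp(-np.abs(tensor.data))))
    out = Tensor(value, (tensor,))
    out._backward = lambda g: _accum(tensor, g * value * (1.0 - value))
    return out


def tanh(tensor: Tensor) -> Tensor:
    tensor = _as_tensor(tensor)
    value = np.tanh(tensor.data)
    out = Tensor(value, (tensor,))
    out._backward = lambda g: _accum(tensor, g * (1.0 - value**2))
    return out


def relu(tensor: Tensor) -> Tensor:
    tensor = _as_tensor(tensor)
    out = Tensor(np.maximum(tensor.data, 0.0), (tensor,))
    out._backward = lambda g: _accum(tensor, g * (tensor.data > 0))
    return out


def silu(tensor: Tensor) -> Tensor:
    tensor = _as_tensor(tensor)
    sig = 1.0 / (1.0 + np.exp(-np.clip(tensor.data, -500, 500)))
    out = Tensor(tensor.data * sig, (tensor,))
    out._backward = lambda g: _accum(
        tensor, g * sig * (1.0 + tensor.data * (1.0 - sig)))
    return out


def softplus(tensor: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x))."""
    tensor = _as_tensor(tensor)
    value = np.maximum(tensor.data, 0.0) + np.log1p(np.exp(-np.abs(tensor.data)))
    out = Tensor(value, (tensor,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(tensor.data, -500, 500)))
    out._backward = lambda g: _accum(tensor, g * sig)
    return out
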