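"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autodiff engine: a :class:`Tensor` wraps an
``ndarray`` and records the operations applied to it; :meth:`Tensor.backward`
walks the tape in reverse topological order and accumulates gradients.
Only the operations the neural-network layers need are implemented, and the
hot paths (softmax, layer normalization, cross-entropy) are fused single
nodes with hand-derived gradients to keep graphs small on CPU.

All arithmetic is float32 unless the caller supplies float64 data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph walk -----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free the tape as we go; grads stay on leaves
                node._backward = None
                node._parents = ()

    def _accumulate(self, grad, own: bool = False):
        # unless `own`, copy: the incoming array may be shared with a sibling
        if self.grad is None:
            if own and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # scalars adopt this tensor's dtype so float32 graphs stay float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g, own=True)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape), own=True)
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape), own=True)

        return Tensor._from_op(a.data / b.data, (a, b), backward)

    def __pow__(self, exponent: float):
        a = self

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1), own=True)

        return Tensor._from_op(a.data**exponent, (a,), backward)

    # -- matmul ---------------------------------------------------------------

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape), own=True)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape), own=True)

        return Tensor._from_op(a.data @ b.data, (a, b), backward)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data, own=True)

        return Tensor._from_op(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data, own=True)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data * out_data), own=True)

        return Tensor._from_op(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _stable_sigmoid(a.data)

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data), own=True)

        return Tensor._from_op(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask, own=True)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        a = self
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = a.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner), own=True)

        return Tensor._from_op(0.5 * x * (1.0 + t), (a,), backward)

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else a.data.shape[axis]

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate((np.broadcast_to(g, a.data.shape) / n).astype(a.data.dtype))

        return Tensor._from_op(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._from_op(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inverse = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(inverse))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, index):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, index, g)
            a._accumulate(full, own=True)

        return Tensor._from_op(a.data[index], (a,), backward)

    def take_rows(self, indices: np.ndarray):
        """Embedding-style lookup: rows of a 2-d table by integer index array."""
        a = self
        indices = np.asarray(indices)

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, indices.reshape(-1), g.reshape(-1, a.data.shape[-1]))
            a._accumulate(full, own=True)

        return Tensor._from_op(a.data[indices], (a,), backward)

    # -- fused ops ------------------------------------------------------------

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot), own=True)

        return Tensor._from_op(out_data, (a,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance, then scale-shift."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        d = a.data.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, d).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, d).sum(axis=0))
            if a.requires_grad:
                gx = g * gamma.data
                term1 = gx
                term2 = gx.mean(axis=-1, keepdims=True)
                term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                a._accumulate(inv * (term1 - term2 - term3), own=True)

        return Tensor._from_op(xhat * gamma.data + beta.data, (a, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`, differentiable in every input."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)
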