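"""A minimal reverse-mode automatic differentiation core over NumPy arrays.

Just enough machinery to express a small encoder–decoder transformer and
differentiate scalar objectives with respect to both its weights and its
input embeddings: broadcast-aware arithmetic, (batched) matmul, softmax,
layer normalization, embedding gather and reductions.  Gradients are
accumulated in float64; every primitive is finite-difference checked in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "layer_norm", "gather_rows", "take_along_last"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        # copy on first accumulation: g may alias a child's grad buffer
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        # for freshly computed gradient arrays that nothing else references
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-propagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad on non-scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            # scalars adopt the operand's dtype (no silent float64 upcast)
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate_owned(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate_owned(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate_owned(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and g.ndim > 2:
                    # batched input x 2-D weight: contract all leading axes
                    lead = list(range(g.ndim - 1))
                    gb = np.tensordot(self.data, g, axes=(lead, lead))
                else:
                    gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                      other.data.shape)
                other._accumulate_owned(gb)

        out._backward = bw
        return out

    # -- elementwise -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(g * mask)

        out._backward = bw
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(g * val)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(g / self.data)

        out._backward = bw
        return out

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate_owned(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate_owned(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(val, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * val).sum(axis=axis, keepdims=True)
            x._accumulate_owned(val * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, parents=(x, gain, bias))
    d = x.data.shape[-1]

    def bw(g):
        if gain.requires_grad:
            gain._accumulate(
                _unbroadcast(g * xhat, gain.data.shape)
            )
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gh = g * gain.data
            term = gh - gh.mean(axis=-1, keepdims=True) - xhat * (
                (gh * xhat).mean(axis=-1, keepdims=True)
            )
            x._accumulate_owned(term * inv)

    out._backward = bw
    return out


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))

    def bw(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate_owned(acc)

    out._backward = bw
    return out


def take_along_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """``np.take_along_axis(x, idx[..., None], -1)`` squeezed, with backward."""
    idx = np.asarray(idx)
    picked = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]
    out = Tensor(picked, parents=(x,))

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.put_along_axis(acc, idx[..., None], g[..., None], axis=-1)
            x._accumulate_owned(acc)

    out._backward = bw
    return out
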