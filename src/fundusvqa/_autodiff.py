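"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for small transformer encoders and MLP heads: broadcasted
arithmetic, matmul, relu, exp/log, reductions, concatenation, slicing,
embedding lookup, softmax/log-softmax and a cross-entropy loss.  Everything is
float64.  Gradients are checked against central finite differences in the test
suite; composite ops (layer norm, softmax) are built from primitives so their
gradients are correct by composition.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], Sequence[Optional[Array]]]] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: Optional[Array] = None

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    # -- shape info --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- operators ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = self.data**exponent
        return Tensor(
            out, (self,), lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bwd(g: Array):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor(a @ b, (self, other), bwd)

    # -- elementwise -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, (self,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), (self,), lambda g: (g / self.data,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: Array):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structural --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        return Tensor(
            self.data.reshape(*shape),
            (self,),
            lambda g: (g.reshape(self.data.shape),),
        )

    def swap_last(self) -> "Tensor":
        return Tensor(
            np.swapaxes(self.data, -1, -2),
            (self,),
            lambda g: (np.swapaxes(g, -1, -2),),
        )

    def __getitem__(self, key) -> "Tensor":
        def bwd(g: Array):
            full = np.zeros_like(self.data)
            full[key] = g
            return (full,)

        return Tensor(self.data[key], (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x: Array) -> Tensor:
    return Tensor(x, requires_grad=True)


# ---------------------------------------------------------------------------
# Composite operations


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array):
        out = []
        for i in range(len(datas)):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(offsets[i], offsets[i + 1])
            out.append(g[tuple(idx)])
        return tuple(out)

    return Tensor(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def embedding(weight: Tensor, ids: Array) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)

    def bwd(g: Array):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        return (gw,)

    return Tensor(weight.data[ids], (weight,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant: no grad path
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps).pow(-0.5)
    return xc * inv * gain + bias


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Scale to unit L2 norm; the zero vector maps to (near) zero."""
    sq = (x * x).sum(axis=axis, keepdims=True)
    return x * (sq + eps).pow(-0.5)


def cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax logits."""
    labels = np.asarray(labels, dtype=np.int64)
    ls = log_softmax(logits, axis=-1)
    picked = ls[np.arange(labels.shape[0]), labels]
    return -picked.mean()
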