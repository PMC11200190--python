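"""Compact reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the encoders, fusion layers and classifier are
built on.  It implements exactly the primitives the model needs — dense
linear algebra, pointwise nonlinearities, reductions, gather/scatter for
graph message passing, a masked softmax and a same-padding 1-D
convolution — each with an analytically coded vector-Jacobian product.
Gradients are verified against central finite differences in the test
suite.

Tensors wrap ``numpy.ndarray`` data; a dynamic tape (the ``_parents``
graph) is walked in reverse topological order by :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverses NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        # float32 passes through untouched (the trainable model runs in
        # single precision); everything else is promoted to float64.
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float64) if arr.dtype != np.float64 else arr
        self.data = arr
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[Array], tuple[Array | None, ...]] | None = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data: Array, parents: Sequence["Tensor"],
              vjp: Callable[[Array], tuple[Array | None, ...]]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
            if node._vjp is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._vjp(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = (pgrad if pgrad.flags.writeable
                                   else pgrad.copy())
                else:
                    parent.grad += pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data + other, (self,), lambda g: (g,))
        o = as_tensor(other)
        return Tensor._make(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape) if self.requires_grad else None,
                       _unbroadcast(g, o.shape) if o.requires_grad else None))

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data - other, (self,), lambda g: (g,))
        o = as_tensor(other)
        return Tensor._make(
            self.data - o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape) if self.requires_grad else None,
                       _unbroadcast(-g, o.shape) if o.requires_grad else None))

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = other
            return Tensor._make(self.data * c, (self,), lambda g: (g * c,))
        o = as_tensor(other)
        return Tensor._make(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.shape)
                       if self.requires_grad else None,
                       _unbroadcast(g * self.data, o.shape)
                       if o.requires_grad else None))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        o = as_tensor(other)
        return Tensor._make(
            self.data / o.data, (self, o),
            lambda g: (_unbroadcast(g / o.data, self.shape)
                       if self.requires_grad else None,
                       _unbroadcast(-g * self.data / o.data ** 2, o.shape)
                       if o.requires_grad else None))

    def __matmul__(self, other):
        o = as_tensor(other)

        def vjp(g: Array):
            ga = (_unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.shape)
                  if self.requires_grad else None)
            gb = (_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.shape)
                  if o.requires_grad else None)
            return ga, gb

        return Tensor._make(self.data @ o.data, (self, o), vjp)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        def vjp(g: Array):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._make(self.data[key], (self,), vjp)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int):
        """Max along ``axis``; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                 axis=axis).squeeze(axis)

        def vjp(g: Array):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            return (full,)

        return Tensor._make(out, (self,), vjp)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0.0), (self,),
                            lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, slope * self.data),
                            (self,), lambda g: (np.where(mask, g, slope * g),))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through unclipped entries."""
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * mask,))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, vjp)


def gather(x: Tensor, index: Array) -> Tensor:
    """Rows of ``x`` at integer ``index`` (any index shape); axis-0 lookup."""
    index = np.asarray(index)

    def vjp(g: Array):
        out = np.zeros_like(x.data)
        np.add.at(out, index, g)
        return (out,)

    return Tensor._make(x.data[index], (x,), vjp)


def segment_sum(x: Tensor, segment_ids: Array, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add)."""
    segment_ids = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + x.shape[1:], dtype=x.data.dtype)
    np.add.at(out, segment_ids, x.data)
    return Tensor._make(out, (x,), lambda g: (g[segment_ids],))


def masked_softmax(logits: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` restricted to positions where ``mask`` is true.

    Masked positions get exactly zero probability.  Rows whose mask is
    entirely false yield all-zero rows (callers zero those outputs anyway).
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), logits.shape)
    e = np.where(mask, logits.data, -np.inf)
    mx = np.max(e, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    np.subtract(e, mx, out=e)
    np.exp(e, out=e)          # masked entries: exp(-inf) underflows to 0
    denom = e.sum(axis=axis, keepdims=True)
    np.divide(e, np.where(denom == 0.0, 1.0, denom), out=e)
    y = e

    def vjp(g: Array):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor._make(y, (logits,), vjp)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 1-D convolution.

    x: (..., L, C_in); weight: (K, C_in, C_out) with K odd; bias: (C_out,).
    Output length equals input length.  Implemented as a sum of shifted
    matrix products, which keeps both directions of the gradient exact.
    """
    K = weight.shape[0]
    if K % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    L = x.shape[-2]
    half = K // 2
    pad_spec = [(0, 0)] * (x.ndim - 2) + [(half, half), (0, 0)]
    xp = np.pad(x.data, pad_spec)
    out = np.zeros(x.shape[:-1] + (weight.shape[2],), dtype=x.data.dtype)
    for k in range(K):
        out += xp[..., k:k + L, :] @ weight.data[k]
    out += bias.data

    def vjp(g: Array):
        gx = gw = gb = None
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[..., k:k + L, :] += g @ weight.data[k].T
            gx = gxp[..., half:half + L, :] if half else gxp
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            ax = tuple(range(g.ndim - 1))
            for k in range(K):
                gw[k] = np.tensordot(xp[..., k:k + L, :], g, axes=(ax, ax))
        if bias.requires_grad:
            gb = g.sum(axis=tuple(range(g.ndim - 1)))
        return gx, gw, gb

    return Tensor._make(out, (x, weight, bias), vjp)


def where_mask(mask: Array, x: Tensor, fill: float = 0.0) -> Tensor:
    """Keep entries of ``x`` where ``mask``; elsewhere the constant ``fill``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        return x
    bmask = np.broadcast_to(mask.reshape(mask.shape + (1,) * (x.ndim - mask.ndim)),
                            x.shape)
    return Tensor._make(np.where(bmask, x.data, fill), (x,),
                        lambda g: (np.where(bmask, g, 0.0),))
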