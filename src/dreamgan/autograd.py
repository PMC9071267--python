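"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations needed by the encoder/generator stack:
elementwise arithmetic with broadcasting, LeakyReLU / tanh / sigmoid,
reductions, strided 2-D convolution and transposed convolution.  Graphs are
built eagerly; calling :meth:`Tensor.backward` on a scalar accumulates
gradients into every reachable tensor with ``requires_grad=True``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "conv2d", "conv_transpose2d"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (forward-only mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(parents)
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return self._make(a.data ** e, (a,), backward)

    # -- nonlinearities -------------------------------------------------------
    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        a = self
        out_data = np.where(a.data > 0, a.data, negative_slope * a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * np.where(a.data > 0, 1.0, negative_slope))

        return self._make(out_data, (a,), backward)

    def tanh(self) -> "Tensor":
        a = self
        t = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - t * t))

        return self._make(t, (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return self._make(s, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def clip(self, lo: float | None = None, hi: float | None = None) -> "Tensor":
        """Clamp values; gradient passes only through unclamped entries."""
        a = self
        out_data = np.clip(a.data, lo, hi)
        inside = np.ones_like(a.data, dtype=bool)
        if lo is not None:
            inside &= a.data > lo
        if hi is not None:
            inside &= a.data < hi

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * inside)

        return self._make(out_data, (a,), backward)

    # -- shape / reductions ---------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -- backward pass --------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # interior node: free memory, keep leaf grads


# -- convolution primitives ---------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(b, C, Hp, Wp) padded input -> (C*k*k, b*ho*wo) patch matrix."""
    b, c = x.shape[:2]
    xt = x.transpose(1, 0, 2, 3)  # (C, b, Hp, Wp) view
    cols = np.empty((c, k, k, b, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xt[:, :, i : i + stride * ho : stride,
                               j : j + stride * wo : stride]
    return cols.reshape(c * k * k, b * ho * wo)


def _col2im(colmat: np.ndarray, c: int, k: int, stride: int, ho: int, wo: int,
            b: int, hp: int, wp: int) -> np.ndarray:
    """Inverse scatter-add of :func:`_im2col`; returns (b, c, hp, wp)."""
    cols = colmat.reshape(c, k, k, b, ho, wo)
    out = np.zeros((c, b, hp, wp), dtype=colmat.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride,
                j : j + stride * wo : stride] += cols[:, i, j]
    return out.transpose(1, 0, 2, 3)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """2-D convolution (cross-correlation); x (B,C,H,W), w (O,C,k,k)."""
    xd, wd = x.data, w.data
    batch, c_in, h, wdt = xd.shape
    o, c_w, k, _ = wd.shape
    if c_in != c_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, kernel {c_w}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wdt + 2 * padding - k) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    colmat = _im2col(xp, k, stride, ho, wo)                    # (Ckk, B*L)
    w2 = wd.reshape(o, -1)
    out = (w2 @ colmat).reshape(o, batch, ho, wo).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, -1)
        if w.requires_grad:
            w._accumulate((gmat @ colmat.T).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = w2.T @ gmat                                 # (Ckk, B*L)
            gxp = _col2im(gcols, c_in, k, stride, ho, wo, batch,
                          h + 2 * padding, wdt + 2 * padding)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """Transposed 2-D convolution; x (B,C,H,W), w (C,O,k,k)."""
    xd, wd = x.data, w.data
    batch, c_in, h, wdt = xd.shape
    c_w, o, k, _ = wd.shape
    if c_in != c_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input {c_in}, kernel {c_w}")
    hp = (h - 1) * stride + k
    wp = (wdt - 1) * stride + k
    xmat = np.ascontiguousarray(xd.transpose(1, 0, 2, 3)).reshape(c_in, -1)
    w2 = wd.reshape(c_in, -1)                                   # (C, Okk)
    cols = np.ascontiguousarray(w2.T) @ xmat                    # (Okk, B*L)
    full = _col2im(cols, o, k, stride, h, wdt, batch, hp, wp)
    out = full[:, :, padding : hp - padding, padding : wp - padding] if padding else full
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else g
        gcols = _im2col(gp, k, stride, h, wdt)                  # (Okk, B*L)
        if w.requires_grad:
            w._accumulate((xmat @ gcols.T).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = (w2 @ gcols).reshape(c_in, batch, h, wdt)
            x._accumulate(gx.transpose(1, 0, 2, 3))

    return Tensor._make(out, parents, backward)
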