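"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs:
elementwise arithmetic with broadcasting, reductions, matrix product,
2-D convolutions (full, depthwise and stride-2 transposed), 2x2 max
pooling, axis max, concatenation and the ReLU/sigmoid nonlinearities.
Gradients are accumulated by topological traversal from the scalar
loss.  All arithmetic is float64, so runs are bit-reproducible for a
fixed seed and gradient checks against central finite differences are
tight (see the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "depthwise_conv2d",
    "matmul",
    "maxpool2x2",
    "amax",
    "relu",
    "replicate_pad2d",
    "sigmoid",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data**(exponent - 1))

        out._backward = bw
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out


# -- nonlinearities -------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


# -- linear algebra -------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def amax(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; gradient flows to the (first) argmax."""
    idx = np.argmax(x.data, axis=axis)
    val = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    out = Tensor(val if keepdims else np.squeeze(val, axis=axis),
                 x.requires_grad, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
        x._accumulate(gx)

    out._backward = bw
    return out


# -- convolutions ---------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW / OCkk layout."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    out_data = np.zeros((n, o, ho, wo))
    for i in range(kh):
        for j in range(kw):
            out_data += np.einsum("oc,nchw->nohw", w.data[:, :, i, j],
                                  xp[:, :, i:i + ho, j:j + wo], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in parents), parents)

    def bw(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += np.einsum(
                        "oc,nohw->nchw", w.data[:, :, i, j], g, optimize=True)
            x._accumulate(gxp[:, :, pad:pad + h, pad:pad + wd]
                          if pad else gxp)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, :, i, j] = np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, i:i + ho, j:j + wo],
                        optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, pad: int = 1) -> Tensor:
    """Per-channel (depth-wise) stride-1 convolution; kernel (C, kh, kw)."""
    n, c, h, wd = x.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    out_data = np.zeros((n, c, ho, wo))
    for i in range(kh):
        for j in range(kw):
            out_data += w.data[None, :, i, j, None, None] * \
                xp[:, :, i:i + ho, j:j + wo]
    out = Tensor(out_data, x.requires_grad or w.requires_grad, (x, w))

    def bw(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += \
                        w.data[None, :, i, j, None, None] * g
            x._accumulate(gxp[:, :, pad:pad + h, pad:pad + wd]
                          if pad else gxp)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, i, j] = np.einsum(
                        "nchw,nchw->c", g, xp[:, :, i:i + ho, j:j + wo],
                        optimize=True)
            w._accumulate(gw)

    out._backward = bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (exact 2x upsampling).

    Kernel layout (C_in, C_out, 2, 2).  Because kernel size equals the
    stride the output blocks never overlap, so the operation is a single
    einsum in both directions.
    """
    n, c, h, wd = x.shape
    ci, o, _, _ = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    y = np.einsum("nchw,cokl->nohkwl", x.data, w.data, optimize=True)
    out_data = y.reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in parents), parents)

    def bw(g):
        gr = g.reshape(n, o, h, 2, wd, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("nohkwl,cokl->nchw", gr, w.data,
                                    optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohkwl->cokl", x.data, gr,
                                    optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def replicate_pad2d(x: Tensor, p: int) -> Tensor:
    """Edge-replicating spatial padding for NCHW tensors."""
    n, c, h, w = x.shape
    out = Tensor(np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                        mode="edge"), x.requires_grad, (x,))
    ri = np.clip(np.arange(h + 2 * p) - p, 0, h - 1)
    ci = np.clip(np.arange(w + 2 * p) - p, 0, w - 1)

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
        x._accumulate(gx)

    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    out._backward = bw
    return out
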