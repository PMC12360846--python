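"""Reverse-mode automatic differentiation over numpy arrays.

Tensors form a DAG; ``Tensor.backward()`` topologically sorts it and runs
each node's backward closure.  Elementwise binary ops require operands of
identical shape (or a python scalar) — there is deliberately no general
broadcasting, which keeps every backward pass a plain accumulation.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode).

    Inside the context every op returns a plain Tensor with no backward
    closure, so intermediate activations are freed as soon as they go out
    of scope.
    """
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple = (),
        _backward: Callable[[], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._prev = _prev
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return self.data.item()

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs get deep for nested U-Nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the closure<->tensor reference cycles so the graph (and all
        # cached activations) is reclaimed by refcounting, not the gc
        for node in topo:
            node._backward = None
            node._prev = ()
            if not node.requires_grad:
                node.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data, parents: tuple, backward) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        return Tensor(data, _prev=parents, _backward=backward)
    return Tensor(data)


def _attach(out: Tensor, back) -> None:
    # only attach the closure when a graph was actually built; otherwise the
    # closure would pin inputs (and itself, cyclically) in inference mode
    if out._prev:
        out._backward = back


# -- elementwise arithmetic ------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))


def add(a: Tensor, b) -> Tensor:
    if isinstance(b, (int, float)):
        out = _make(a.data + b, (a,), None)

        def back():
            a._accumulate(out.grad)

        _attach(out, back)
        return out
    b = _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.shape} vs {b.shape}")
    out = _make(a.data + b.data, (a, b), None)

    def back2():
        a._accumulate(out.grad)
        b._accumulate(out.grad)

    _attach(out, back2)
    return out


def sub(a: Tensor, b) -> Tensor:
    if isinstance(b, (int, float)):
        out = _make(a.data - b, (a,), None)

        def back():
            a._accumulate(out.grad)

        _attach(out, back)
        return out
    b = _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in sub: {a.shape} vs {b.shape}")
    out = _make(a.data - b.data, (a, b), None)

    def back2():
        a._accumulate(out.grad)
        b._accumulate(-out.grad)

    _attach(out, back2)
    return out


def mul(a: Tensor, b) -> Tensor:
    if isinstance(b, (int, float)):
        out = _make(a.data * b, (a,), None)

        def back():
            a._accumulate(out.grad * b)

        _attach(out, back)
        return out
    b = _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in mul: {a.shape} vs {b.shape}")
    out = _make(a.data * b.data, (a, b), None)

    def back2():
        a._accumulate(out.grad * b.data)
        b._accumulate(out.grad * a.data)

    _attach(out, back2)
    return out


def neg(a: Tensor) -> Tensor:
    out = _make(-a.data, (a,), None)

    def back():
        a._accumulate(-out.grad)

    _attach(out, back)
    return out


def log(a: Tensor) -> Tensor:
    out = _make(np.log(a.data), (a,), None)

    def back():
        a._accumulate(out.grad / a.data)

    _attach(out, back)
    return out


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    clipped = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)
    out = _make(clipped, (a,), None)

    def back():
        a._accumulate(out.grad * mask)

    _attach(out, back)
    return out


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    out = _make(np.asarray(a.data.mean()), (a,), None)

    def back():
        a._accumulate(np.full_like(a.data, out.grad / n))

    _attach(out, back)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = _make(a.data * mask, (a,), None)

    def back():
        a._accumulate(out.grad * mask)

    _attach(out, back)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(s, (a,), None)

    def back():
        a._accumulate(out.grad * s * (1.0 - s))

    _attach(out, back)
    return out


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with one learnable slope per channel (axis 1 of x)."""
    c = x.data.shape[1]
    if alpha.data.shape != (c,):
        raise ValueError(f"alpha must have shape ({c},), got {alpha.data.shape}")
    a_b = alpha.data.reshape((1, c) + (1,) * (x.data.ndim - 2))
    pos = x.data > 0
    out_data = np.where(pos, x.data, a_b * x.data)
    out = _make(out_data, (x, alpha), None)

    def back():
        g = out.grad
        dx = np.where(pos, g, a_b * g)
        x._accumulate(dx)
        reduce_axes = (0,) + tuple(range(2, x.data.ndim))
        da = np.where(pos, 0.0, g * x.data).sum(axis=reduce_axes)
        alpha._accumulate(da.astype(_DTYPE))

    _attach(out, back)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _make(np.concatenate(datas, axis=axis), tuple(tensors), None)
    sizes = [d.shape[axis] for d in datas]

    def back():
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accumulate(g)

    _attach(out, back)
    return out


# -- dense / pooling layers ------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F), w: (F, O), b: (O,)."""
    out = _make(x.data @ w.data + b.data, (x, w, b), None)

    def back():
        g = out.grad
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)
        b._accumulate(g.sum(axis=0))

    _attach(out, back)
    return out


def global_mean_pool(x: Tensor) -> Tensor:
    """Adaptive average pool to 1³ then flatten: (N, C, D, H, W) -> (N, C)."""
    n_spatial = int(np.prod(x.data.shape[2:]))
    out = _make(x.data.mean(axis=(2, 3, 4)), (x,), None)

    def back():
        g = out.grad[:, :, None, None, None] / n_spatial
        x._accumulate(np.broadcast_to(g, x.data.shape))

    _attach(out, back)
    return out


def maxpool3d(x: Tensor) -> Tensor:
    """Max pooling with kernel 2, stride 2; spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d requires even spatial dims, got {(d, h, w)}")
    blocks = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // 2, h // 2, w // 2, 8
    )
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    out = _make(out_data, (x,), None)

    def back():
        g = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=_DTYPE)
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
        g = g.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        x._accumulate(g)

    _attach(out, back)
    return out


def _upsample_axis_weights(n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # align_corners=False mapping for scale factor 2
    coord = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
    i0 = np.floor(coord).astype(np.int64)
    frac = (coord - i0).astype(_DTYPE)
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def _upsample_one_axis(a: np.ndarray, axis: int) -> np.ndarray:
    i0, i1, frac = _upsample_axis_weights(a.shape[axis])
    shape = [1] * a.ndim
    shape[axis] = len(frac)
    w = frac.reshape(shape)
    return np.take(a, i0, axis=axis) * (1 - w) + np.take(a, i1, axis=axis) * w


def _downsample_adjoint_one_axis(g: np.ndarray, axis: int, n_in: int) -> np.ndarray:
    i0, i1, frac = _upsample_axis_weights(n_in)
    shape = [1] * g.ndim
    shape[axis] = len(frac)
    w = frac.reshape(shape)
    out_shape = list(g.shape)
    out_shape[axis] = n_in
    out = np.zeros(out_shape, dtype=_DTYPE)
    gm = np.moveaxis(out, axis, 0)
    np.add.at(gm, i0, np.moveaxis(g * (1 - w), axis, 0))
    np.add.at(gm, i1, np.moveaxis(g * w, axis, 0))
    return out


def upsample3d(x: Tensor) -> Tensor:
    """Trilinear upsampling by a factor of 2 (align_corners=False)."""
    in_spatial = x.data.shape[2:]
    y = x.data
    for axis in (2, 3, 4):
        y = _upsample_one_axis(y, axis)
    out = _make(y.astype(_DTYPE), (x,), None)

    def back():
        g = out.grad
        for axis in (4, 3, 2):
            g = _downsample_adjoint_one_axis(g, axis, in_spatial[axis - 2])
        x._accumulate(g)

    _attach(out, back)
    return out


# -- convolution -----------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution; x: (N, C, D, H, W), w: (O, C, K, K, K), b: (O,).

    Implemented as K³ shift-accumulate channel GEMMs — for each kernel
    offset the padded input is sliced and contracted over channels — which
    keeps peak memory at one channel-slice copy instead of a full im2col
    matrix.
    """
    n, c, d, h, wdt = x.data.shape
    o, c2, kd, kh, kw = w.data.shape
    if c2 != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {c2}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    do = (d + 2 * p - kd) // s + 1
    ho = (h + 2 * p - kh) // s + 1
    wo = (wdt + 2 * p - kw) // s + 1

    out_data = np.empty((o, n, do, ho, wo), dtype=_DTYPE)
    out_data[:] = b.data[:, None, None, None, None]
    for kz in range(kd):
        for ky in range(kh):
            for kx in range(kw):
                sl = xp[
                    :, :, kz : kz + s * do : s, ky : ky + s * ho : s, kx : kx + s * wo : s
                ]
                # (O, C) x (N, C, do, ho, wo) -> (O, N, do, ho, wo)
                out_data += np.tensordot(w.data[:, :, kz, ky, kx], sl, axes=([1], [1]))
    out = _make(np.ascontiguousarray(out_data.transpose(1, 0, 2, 3, 4)), (x, w, b), None)

    def back():
        g = out.grad  # (N, O, do, ho, wo)
        b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for kz in range(kd):
            for ky in range(kh):
                for kx in range(kw):
                    sl = xp[
                        :, :, kz : kz + s * do : s, ky : ky + s * ho : s, kx : kx + s * wo : s
                    ]
                    # dW[o, c] = sum_{n, spatial} g[n, o, ...] * x[n, c, ...]
                    dw[:, :, kz, ky, kx] = np.tensordot(
                        g, sl, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    # dx_slice[n, c] += sum_o g[n, o] W[o, c]
                    dxp[
                        :, :, kz : kz + s * do : s, ky : ky + s * ho : s, kx : kx + s * wo : s
                    ] += np.tensordot(g, w.data[:, :, kz, ky, kx], axes=([1], [0])).transpose(
                        0, 4, 1, 2, 3
                    )
        w._accumulate(dw)
        dx = dxp[:, :, p : p + d, p : p + h, p : p + wdt] if p else dxp
        x._accumulate(np.ascontiguousarray(dx))

    _attach(out, back)
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-(sample, channel) normalization over the spatial dims with affine."""
    axes = tuple(range(2, x.data.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    c = x.data.shape[1]
    gshape = (1, c) + (1,) * (x.data.ndim - 2)
    out = _make(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape), (x, gamma, beta), None)

    def back():
        g = out.grad
        reduce_nc = (0,) + axes
        gamma._accumulate((g * xhat).sum(axis=reduce_nc))
        beta._accumulate(g.sum(axis=reduce_nc))
        dxhat = g * gamma.data.reshape(gshape)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(inv * (dxhat - m1 - xhat * m2))

    _attach(out, back)
    return out


# -- losses ----------------------------------------------------------------


def smooth_l1_loss(x: Tensor, y: Tensor) -> Tensor:
    """Mean Huber loss with threshold 1: 0.5 d² below, |d| − 0.5 above."""
    if x.data.shape != y.data.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x.data.astype(np.float64) - y.data.astype(np.float64)
    absd = np.abs(d)
    small = absd < 1.0
    vals = np.where(small, 0.5 * d * d, absd - 0.5)
    n = d.size
    out = _make(np.asarray(vals.mean()), (x, y), None)

    def back():
        g = out.grad / n
        dd = (np.where(small, d, np.sign(d)) * g).astype(_DTYPE)
        x._accumulate(dd)
        y._accumulate(-dd)

    _attach(out, back)
    return out
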