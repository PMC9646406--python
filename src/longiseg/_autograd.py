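"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the 3D encoder-decoder
segmentation networks in this package: padded 3x3x3 (and pointwise)
convolutions, 2x2x2 stride-2 convolutions and transposed convolutions,
group normalization, LeakyReLU, channel concatenation, softmax, and the
elementwise/reduction primitives the Dice and focal losses are built from.

Design notes
------------
* Define-by-run graph: every op returns a new :class:`Tensor` holding a
  closure that scatters the incoming gradient to its parents. ``backward``
  runs an iterative topological sort (no recursion limits).
* Convolutions are lowered to BLAS calls via ``sliding_window_view`` +
  ``tensordot``; the 2x2x2 stride-2 (de)convolutions exploit the fact that
  their windows tile the grid exactly, so they reduce to reshapes.
* dtype is preserved end to end: float32 for training, float64 tensors can
  be used for finite-difference gradient checking.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "add", "sub", "mul", "div", "scale", "add_const",
    "power", "log", "clip", "leaky_relu", "concat", "softmax", "tsum", "tmean",
    "conv3d", "conv_down2", "conv_up2", "group_norm",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward_fn: Callable | None = None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        _accum(self, grad)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor holding trainable weights."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(a.data + b.data, parents=(a, b), backward_fn=bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, g)
        _accum(b, -g)

    return Tensor(a.data - b.data, parents=(a, b), backward_fn=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return Tensor(a.data * b.data, parents=(a, b), backward_fn=bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data * b.data))

    return Tensor(a.data / b.data, parents=(a, b), backward_fn=bw)


def scale(a: Tensor, s: float) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g * s)

    return Tensor(a.data * s, parents=(a,), backward_fn=bw)


def add_const(a: Tensor, c: float) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g)

    return Tensor(a.data + c, parents=(a,), backward_fn=bw)


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    out = a.data ** p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return Tensor(out, parents=(a,), backward_fn=bw)


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g / a.data)

    return Tensor(np.log(a.data), parents=(a,), backward_fn=bw)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes through only inside the (closed) interval."""
    a = _as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)

    def bw(g):
        _accum(a, g * inside)

    return Tensor(out, parents=(a,), backward_fn=bw)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    a = _as_tensor(a)
    pos = a.data > 0
    out = np.where(pos, a.data, slope * a.data)

    def bw(g):
        _accum(a, g * np.where(pos, 1.0, slope).astype(a.dtype))

    return Tensor(out, parents=(a,), backward_fn=bw)


def tsum(a: Tensor, axis=None) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis)
    axes = axis if axis is None else (
        (axis,) if np.isscalar(axis) else tuple(axis))

    def bw(g):
        if axes is None:
            _accum(a, np.broadcast_to(g, a.data.shape).astype(a.dtype))
        else:
            gexp = np.expand_dims(g, axes)
            _accum(a, np.broadcast_to(gexp, a.data.shape).astype(a.dtype))

    return Tensor(out, parents=(a,), backward_fn=bw)


def tmean(a: Tensor, axis=None) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return scale(tsum(a, axis=axis), 1.0 / float(n))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward_fn=bw)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(a, y * (g - dot))

    return Tensor(y, parents=(a,), backward_fn=bw)


# ---------------------------------------------------------------------------
# convolutions and normalization
# ---------------------------------------------------------------------------

def _gather(arr_b: np.ndarray, k: int, p: int, spatial) -> np.ndarray:
    """(C, X', Y', Z') padded grid -> contiguous (k^3 * C, X*Y*Z) matrix.

    Row order is (offset-major, channel-minor); each stacked slice copies
    long z-contiguous runs, which keeps the gather memcpy-bound.
    """
    X, Y, Z = spatial
    if p:
        arr_b = np.pad(arr_b, ((0, 0), (p, p), (p, p), (p, p)))
    C = arr_b.shape[0]
    out = np.empty((k ** 3, C, X, Y, Z), dtype=arr_b.dtype)
    n = 0
    for i in range(k):
        for j in range(k):
            for kz in range(k):
                out[n] = arr_b[:, i:i + X, j:j + Y, kz:kz + Z]
                n += 1
    return out.reshape(k ** 3 * C, X * Y * Z)


def _weight_matrix(w: np.ndarray, flip: bool) -> np.ndarray:
    """(O, C, k, k, k) -> (O, k^3 * C) matching the _gather row order."""
    if flip:
        w = w[:, :, ::-1, ::-1, ::-1]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1)).reshape(
        w.shape[0], -1)


def conv3d(x: Tensor, w: Tensor, b: Tensor, padding: int | None = None) -> Tensor:
    """3D convolution, stride 1, 'same'-style symmetric zero padding.

    x: (B, C, X, Y, Z); w: (O, C, k, k, k); b: (O,). Lowered to one GEMM
    per batch element; the gathered patch matrix is kept for the weight
    gradient, and the input gradient is the full convolution with the
    flipped kernel, computed by the same lowering.
    """
    k = w.data.shape[-1]
    O, C = w.data.shape[:2]
    p = (k - 1) // 2 if padding is None else padding
    B = x.data.shape[0]
    spatial = x.data.shape[2:]
    n_vox = int(np.prod(spatial))
    wm = _weight_matrix(w.data, flip=False)
    cols = [_gather(x.data[i], k, p, spatial) for i in range(B)]
    out = np.empty((B, O) + tuple(spatial), dtype=x.dtype)
    for i in range(B):
        out[i] = (wm @ cols[i]).reshape((O,) + tuple(spatial))
    out += b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            dwm = np.zeros_like(wm)
            for i in range(B):
                dwm += g[i].reshape(O, n_vox) @ cols[i].T
            dw = dwm.reshape(O, k, k, k, C).transpose(0, 4, 1, 2, 3)
            _accum(w, np.ascontiguousarray(dw))
        if x.requires_grad:
            q = k - 1 - p
            wf = _weight_matrix(np.ascontiguousarray(
                w.data.transpose(1, 0, 2, 3, 4)), flip=True)
            dx = np.empty_like(x.data)
            for i in range(B):
                gcols = _gather(g[i], k, q, spatial)
                dx[i] = (wf @ gcols).reshape((C,) + tuple(spatial))
            _accum(x, dx)

    return Tensor(out, parents=(x, w, b), backward_fn=bw)


def conv_down2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 convolution with stride 2 (downsampler). Spatial dims must be even."""
    B, C, X, Y, Z = x.data.shape
    xb = x.data.reshape(B, C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    out = np.tensordot(xb, w.data, axes=([1, 3, 5, 7], [1, 2, 3, 4]))
    out = np.moveaxis(out, -1, 1) + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            dw = np.tensordot(g, xb, axes=([0, 2, 3, 4], [0, 2, 4, 6]))
            _accum(w, dw)
        if x.requires_grad:
            dxb = np.tensordot(g, w.data, axes=([1], [0]))  # (B,X,Y,Z,C,i,j,k)
            dxb = np.transpose(dxb, (0, 4, 1, 5, 2, 6, 3, 7))
            _accum(x, dxb.reshape(B, C, X, Y, Z))

    return Tensor(out.astype(x.dtype, copy=False), parents=(x, w, b), backward_fn=bw)


def conv_up2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (upsampler).

    w: (C_in, O, 2, 2, 2) following the transposed-conv weight convention.
    """
    B, C, X, Y, Z = x.data.shape
    O = w.data.shape[1]
    blocks = np.tensordot(x.data, w.data, axes=([1], [0]))  # (B,X,Y,Z,O,i,j,k)
    blocks = np.transpose(blocks, (0, 4, 1, 5, 2, 6, 3, 7))
    out = blocks.reshape(B, O, 2 * X, 2 * Y, 2 * Z) + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        gb = g.reshape(B, O, X, 2, Y, 2, Z, 2)
        if w.requires_grad:
            dw = np.tensordot(x.data, gb, axes=([0, 2, 3, 4], [0, 2, 4, 6]))
            _accum(w, dw)
        if x.requires_grad:
            dx = np.tensordot(gb, w.data, axes=([1, 3, 5, 7], [1, 2, 3, 4]))
            _accum(x, np.moveaxis(dx, -1, 1))

    return Tensor(out.astype(x.dtype, copy=False), parents=(x, w, b), backward_fn=bw)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, n_groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over channel groups and all spatial positions."""
    B, C = x.data.shape[:2]
    if C % n_groups:
        raise ValueError(f"channels ({C}) not divisible by n_groups ({n_groups})")
    xr = x.data.reshape(B, n_groups, -1)
    mu = xr.mean(axis=-1, keepdims=True)
    var = xr.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat_r = (xr - mu) * inv
    xhat = xhat_r.reshape(x.data.shape)
    cshape = (1, C) + (1,) * (x.data.ndim - 2)
    out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def bw(g):
        reduce_axes = (0,) + tuple(range(2, x.data.ndim))
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=reduce_axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=reduce_axes))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(cshape)).reshape(B, n_groups, -1)
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat_r).mean(axis=-1, keepdims=True)
            dx = inv * (dxhat - m1 - xhat_r * m2)
            _accum(x, dx.reshape(x.data.shape).astype(x.dtype, copy=False))

    return Tensor(out.astype(x.dtype, copy=False),
                  parents=(x, gamma, beta), backward_fn=bw)
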