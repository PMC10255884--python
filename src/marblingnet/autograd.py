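"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation network needs: 2-D
convolution (with dilation), 2x2 stride-2 transposed convolution, max
pooling with stride = window, batch normalization, ReLU, bilinear
resizing, channel concatenation, spatial cropping and elementwise
arithmetic.  All tensors are float32; gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.

The engine is intentionally small: a :class:`Tensor` records its parents
and a closure that propagates the upstream gradient.  There is no graph
retention across backward calls and no higher-order differentiation.
Inference runs inside :func:`no_grad`, which drops the tape (and the
im2col buffers it would otherwise pin in memory).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "conv2d", "conv_transpose2x2", "max_pool",
           "batch_norm", "relu", "bilinear_resize", "concat", "crop2d"]

_F32 = np.float32
_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy float32 array plus an autograd tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=_F32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return _node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return _node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def sum(self):
        a = self
        return _node(a.data.sum(), (a,),
                     lambda g: a._accumulate(np.broadcast_to(g, a.data.shape)))

    def reshape(self, *shape):
        a = self
        out_shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        return _node(a.data.reshape(out_shape), (a,),
                     lambda g: a._accumulate(g.reshape(a.data.shape)))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _node(out: np.ndarray, parents: Sequence[Tensor], bw) -> Tensor:
    """Build a graph node, or a detached tensor when no gradient can flow."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(out, parents=parents, backward=bw)
    return Tensor(out)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# spatial operations on NCHW tensors
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) columns for a 'same' k x k convolution."""
    n, c, h, w = x.shape
    p = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki * k + kj] = xp[:, :, ki * dilation:ki * dilation + h,
                                         kj * dilation:kj * dilation + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add columns back)."""
    n, c, h, w = xshape
    p = dilation * (k - 1) // 2
    gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
    cols = cols.reshape(n, c, k, k, h, w)
    for ki in range(k):
        for kj in range(k):
            gx[:, :, ki * dilation:ki * dilation + h,
               kj * dilation:kj * dilation + w] += cols[:, :, ki, kj]
    return gx[:, :, p:p + h, p:p + w] if p else gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """'Same' 2-D convolution (cross-correlation), odd kernel, stride 1.

    x: (N,C,H,W); w: (O,C,k,k); b: (O,) or None.
    """
    n, c, h, wd = x.data.shape
    o, ci, k, k2 = w.data.shape
    if ci != c or k != k2 or k % 2 == 0:
        raise ValueError(
            f"conv2d weight shape {w.data.shape} incompatible with input {x.data.shape}")
    cols = _im2col(x.data, k, dilation)                       # (N, C*k*k, HW)
    wm = w.data.reshape(o, c * k * k)
    out = np.matmul(wm, cols).reshape(n, o, h, wd)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        gm = g.reshape(n, o, h * wd)
        if w.requires_grad:
            gw = np.matmul(gm, cols.swapaxes(1, 2)).sum(axis=0)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wm.T, gm)                       # (N, C*k*k, HW)
            x._accumulate(_col2im(gcols, (n, c, h, wd), k, dilation))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (learned x2 upsampling).

    x: (N,C,H,W); w: (C,O,2,2); output (N,O,2H,2W).  Windows do not
    overlap at stride 2, so the op is an einsum plus interleave.
    """
    n, c, h, wd = x.data.shape
    ci, o, k, k2 = w.data.shape
    if ci != c or (k, k2) != (2, 2):
        raise ValueError("conv_transpose2x2 expects (C,O,2,2) weights")
    out = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out = np.ascontiguousarray(out).reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        g6 = g.reshape(n, o, h, 2, wd, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("nohiwj,nchw->coij", g6, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def max_pool(x: Tensor, k: int) -> Tensor:
    """Max pooling with window k and stride k; ragged edges padded with -inf."""
    n, c, h, w = x.data.shape
    ph, pw = (-h) % k, (-w) % k
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)),
                constant_values=-np.inf) if (ph or pw) else x.data
    hh, ww = xp.shape[2] // k, xp.shape[3] // k
    blocks = xp.reshape(n, c, hh, k, ww, k)
    out = blocks.max(axis=(3, 5))

    def bw(g):
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, k * k)
        first = flat.argmax(axis=-1)        # ties -> first element (deterministic)
        sel = np.zeros(flat.shape, dtype=_F32)
        np.put_along_axis(sel, first[..., None], 1.0, axis=-1)
        gx = (sel * g[..., None]).reshape(n, c, hh, ww, k, k)
        gx = gx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh * k, ww * k)
        x._accumulate(gx[:, :, :h, :w])

    return _node(out, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _node(x.data * mask, (x,), lambda g: x._accumulate(g * mask))


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on NCHW with running statistics."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = (1.0 / np.sqrt(var + eps)).astype(_F32)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                gmean = gi.mean(axis=(0, 2, 3))
                gdot = (gi * xhat).mean(axis=(0, 2, 3))
                gx = (gi - gmean[None, :, None, None]
                      - xhat * gdot[None, :, None, None]) * inv[None, :, None, None]
            else:
                gx = gi * inv[None, :, None, None]
            x._accumulate(gx.astype(_F32))

    return _node(out, (x, gamma, beta), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in), dtype=_F32)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (src - lo).astype(_F32)
    np.add.at(a, (np.arange(n_out), lo), 1 - t)
    np.add.at(a, (np.arange(n_out), hi), t)
    return a


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling of NCHW to spatial ``size`` (separable matrices)."""
    ho, wo = size
    ah = _interp_matrix(ho, x.data.shape[2])
    aw = _interp_matrix(wo, x.data.shape[3])
    out = np.einsum("Hh,nchw,Ww->ncHW", ah, x.data, aw, optimize=True)

    def bw(g):
        x._accumulate(np.einsum("Hh,ncHW,Ww->nchw", ah, g, aw, optimize=True))

    return _node(out, (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return _node(out, tuple(tensors), bw)


def crop2d(x: Tensor, top: int, left: int, height: int, width: int) -> Tensor:
    """Spatial crop of NCHW (used to trim padding before the loss)."""
    out = x.data[:, :, top:top + height, left:left + width]

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, :, top:top + height, left:left + width] = g
        x._accumulate(gx)

    return _node(out.copy(), (x,), bw)
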