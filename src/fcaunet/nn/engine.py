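"""A small reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the attention U-Net needs: dense and
depthwise 2-D cross-correlation (im2col based), pooling, nearest and
bilinear upsampling, batch normalization, the usual pointwise
nonlinearities, softmax, matrix products and reductions.  Tensors form
a tape; :meth:`Tensor.backward` walks it in reverse topological order.
Gradients are retained on every node, which Grad-CAM relies on to read
the gradient of a class score with respect to an intermediate feature
map.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

Array = np.ndarray


class Tensor:
    """Array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents, backward, requires) -> Tensor:
    return Tensor(data, requires_grad=requires,
                  parents=parents if requires else (),
                  backward=backward if requires else None)


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward, _needs(a, b))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward, _needs(a, b))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), backward, _needs(a, b))


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(orig))

    return _make(out_data, (a,), backward, a.requires_grad)


def transpose(a: Tensor, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    out_data = a.data.transpose(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(out_data, (a,), backward, a.requires_grad)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tuple(ts), backward, _needs(*ts))


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward, a.requires_grad)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * s * (1.0 - s))

    return _make(s, (a,), backward, a.requires_grad)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return _make(s, (a,), backward, a.requires_grad)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.data.size / out_data.size

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        a._accum(np.broadcast_to(g, a.data.shape) / denom)

    return _make(out_data, (a,), backward, a.requires_grad)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward, a.requires_grad)


# -- convolution machinery --------------------------------------------


def _im2col(x: Array, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> windows (N, C, kh, kw, Hout, Wout) as a view-copy."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    hout = (h - kh) // stride + 1
    wout = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Hout, Wout, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)), hout, wout, x.shape


def _col2im(cols: Array, padded_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter window gradients back to the (padded) input grid."""
    n, c, hp, wp = padded_shape
    out = np.zeros(padded_shape, dtype=np.float64)
    hout, wout = cols.shape[-2], cols.shape[-1]
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * hout:stride, j:j + stride * wout:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:hp - pad, pad:wp - pad]
    return out


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Dense cross-correlation. x:(N,Cin,H,W), w:(Cout,Cin,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    co, ci, kh, kw = w.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(f"conv2d channel mismatch: input {x.data.shape[1]}, kernel {ci}")
    cols, hout, wout, padded_shape = _im2col(x.data, kh, kw, stride, pad)
    out_data = np.einsum("ncijhw,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + as_tensor(b).data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nohw,ncijhw->ocij", g, cols, optimize=True))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nohw,ocij->ncijhw", g, w.data, optimize=True)
            x._accum(_col2im(dcols, padded_shape, kh, kw, stride, pad))

    return _make(out_data, parents, backward, _needs(*parents))


def depthwise_conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Per-channel cross-correlation. x:(N,C,H,W), w:(C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    c, kh, kw = w.data.shape
    if x.data.shape[1] != c:
        raise ValueError("depthwise channel mismatch")
    cols, hout, wout, padded_shape = _im2col(x.data, kh, kw, stride, pad)
    out_data = np.einsum("ncijhw,cij->nchw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + as_tensor(b).data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nchw,ncijhw->cij", g, cols, optimize=True))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nchw,cij->ncijhw", g, w.data, optimize=True)
            x._accum(_col2im(dcols, padded_shape, kh, kw, stride, pad))

    return _make(out_data, parents, backward, _needs(*parents))


def avg_pool2d(x: Tensor, k: int = 2, stride: Optional[int] = None, pad: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or k
    cols, hout, wout, padded_shape = _im2col(x.data, k, k, stride, pad)
    out_data = cols.mean(axis=(2, 3))

    def backward(g):
        dcols = np.broadcast_to(
            g[:, :, None, None], (g.shape[0], g.shape[1], k, k) + g.shape[2:]
        ) / (k * k)
        x._accum(_col2im(dcols, padded_shape, k, k, stride, pad))

    return _make(out_data, (x,), backward, x.requires_grad)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("max_pool2d requires H, W divisible by the window")
    r = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]
    # resolve ties deterministically: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    first = np.zeros_like(flat, dtype=np.float64)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], 1.0, axis=-1)
    first = first.reshape(n, c, h // k, w // k, k, k)

    def backward(g):
        gexp = g[:, :, :, :, None, None] * first
        x._accum(gexp.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))

    return _make(out_data, (x,), backward, x.requires_grad)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward, x.requires_grad)


def _bilinear_weights(size_in: int, scale: int):
    """Source indices and weights for align_corners=False interpolation."""
    size_out = size_in * scale
    pos = (np.arange(size_out) + 0.5) / scale - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, size_in - 1)
    i1 = np.clip(i0 + 1, 0, size_in - 1)
    t = np.clip(pos - np.floor(pos), 0.0, 1.0)
    t[pos < 0] = 0.0
    t[pos > size_in - 1] = 0.0
    return i0, i1, t


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    r0, r1, ty = _bilinear_weights(h, scale)
    c0, c1, tx = _bilinear_weights(w, scale)
    ty_ = ty[:, None]
    tx_ = tx[None, :]
    d = x.data
    out_data = ((1 - ty_) * ((1 - tx_) * d[:, :, r0][:, :, :, c0] + tx_ * d[:, :, r0][:, :, :, c1])
                + ty_ * ((1 - tx_) * d[:, :, r1][:, :, :, c0] + tx_ * d[:, :, r1][:, :, :, c1]))

    def backward(g):
        dx = np.zeros_like(x.data)
        for rr, wy in ((r0, 1 - ty), (r1, ty)):
            for cc, wx in ((c0, 1 - tx), (c1, tx)):
                contrib = g * wy[:, None] * wx[None, :]
                np.add.at(dx, (slice(None), slice(None), rr[:, None], cc[None, :]), contrib)
        x._accum(dx)

    return _make(out_data, (x,), backward, x.requires_grad)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: Array, running_var: Array,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalization over (N, H, W).

    Updates ``running_mean``/``running_var`` in place while training.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gk = g * gamma.data[None, :, None, None]
            if training:
                term = (gk - gk.mean(axis=axes)[None, :, None, None]
                        - xhat * (gk * xhat).mean(axes)[None, :, None, None])
                x._accum(term * inv[None, :, None, None])
            else:
                x._accum(gk * inv[None, :, None, None])

    return _make(out_data, (x, gamma, beta), backward, _needs(x, gamma, beta))


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    x = as_tensor(x)
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep

    def backward(g):
        x._accum(g * mask)

    return _make(x.data * mask, (x,), backward, x.requires_grad)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return mean(x, axis=(2, 3))


def cross_entropy_logits(logits: Tensor, targets: Array,
                         class_weights: Optional[Array] = None) -> Tensor:
    """Mean (optionally class-weighted) cross-entropy from raw logits."""
    logits = as_tensor(logits)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[targets]
    loss = -(w * logp[np.arange(n), targets]).sum() / w.sum()

    def backward(g):
        p = np.exp(logp)
        dl = p.copy()
        dl[np.arange(n), targets] -= 1.0
        dl *= (w / w.sum())[:, None]
        logits._accum(g * dl)

    return _make(np.asarray(loss), (logits,), backward, logits.requires_grad)
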