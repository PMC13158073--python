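"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives a 2-D convolutional encoder-decoder needs:
elementwise arithmetic with broadcasting, reductions, activations, stride-1
"same"-padded 2-D convolution (standard / dilated / grouped / depthwise /
pointwise), a 1-D channel-descriptor convolution, 2x2 max pooling, stride-1
3x3 max pooling, factor-f average pooling, batch normalization, bilinear 2x
upsampling and 2x2 transposed convolution.

All convolutions here are stride 1 with zero padding sized to preserve the
spatial extent; spatial downsampling in a network is done by pooling. This
constraint makes the input-gradient of every convolution itself a same-padded
convolution with the spatially flipped kernel, which keeps the backward pass
as fast as the forward pass (no scatter-add col2im).

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  Wrap inference
code in :func:`no_grad` to skip graph construction entirely.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "conv2d",
    "conv1d_channels",
    "conv_transpose2d_2x",
    "batch_norm",
    "max_pool2d",
    "max_pool_same",
    "avg_pool2d",
    "upsample_bilinear_2x",
    "concat",
    "sigmoid",
    "relu",
    "log",
    "exp",
    "clip",
]

_grad_enabled = True

# When not None, conv primitives accumulate multiply-add counts here
# (a one-element list used as a mutable cell by complexity reporting).
_mac_counter = None


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / counting mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads eagerly; keep leaves
                if node._parents:
                    node.grad = None if node is not self else node.grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _binary(_wrap(other), self, np.subtract, lambda g, a, b: (g, -g))

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return _binary(
            _wrap(other), self, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __neg__(self):
        return _unary(self, np.negative, lambda g, x, y: -g)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return _unary(self, lambda x: x**p, lambda g, x, y: g * p * x ** (p - 1))

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        x = self

        def fwd(a):
            return np.sum(a, axis=axis, keepdims=keepdims)

        def bwd(g, a, y):
            if axis is None:
                return np.broadcast_to(g, a.shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, a.shape).copy()

        return _unary(x, fwd, bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        x = self

        def bwd(g, a, y):
            return g.reshape(a.shape)

        return _unary(x, lambda a: a.reshape(shape), bwd)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    g = g.astype(t.data.dtype, copy=False)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or not g.flags.owndata else g
    else:
        t.grad = t.grad + g


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    ad_, bd = a.data, b.data
    # keep 0-d python-scalar operands from upcasting float32 graphs
    if ad_.dtype != bd.dtype:
        if bd.ndim == 0 and ad_.ndim > 0:
            bd = bd.astype(ad_.dtype)
        elif ad_.ndim == 0 and bd.ndim > 0:
            ad_ = ad_.astype(bd.dtype)
    out_data = fwd(ad_, bd)

    def backward(g):
        ga, gb = grads(g, a.data, b.data)
        if a.requires_grad:
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def _unary(x, fwd, bwd) -> Tensor:
    x = _wrap(x)
    y = fwd(x.data)

    def backward(g):
        if x.requires_grad:
            _accum(x, bwd(g, x.data, y))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0), lambda g, a, y: g * (a > 0))


def sigmoid(x):
    def fwd(a):
        out = np.empty_like(a)
        pos = a >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
        ea = np.exp(a[~pos])
        out[~pos] = ea / (1.0 + ea)
        return out

    return _unary(x, fwd, lambda g, a, y: g * y * (1.0 - y))


def log(x):
    if isinstance(x, Tensor):
        return _unary(x, np.log, lambda g, a, y: g / a)
    return np.log(x)


def exp(x):
    if isinstance(x, Tensor):
        return _unary(x, np.exp, lambda g, a, y: g * y)
    return np.exp(x)


def clip(x, lo, hi):
    if isinstance(x, Tensor):
        return _unary(
            x,
            lambda a: np.clip(a, lo, hi),
            lambda g, a, y: g * ((a >= lo) & (a <= hi)),
        )
    return np.clip(x, lo, hi)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                _accum(t, g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolutions (stride 1, "same" zero padding, odd kernels)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int, pad: int) -> np.ndarray:
    """Return patch matrix of shape [B, C*k*k, H*W] for a stride-1 conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, k, k, H, W),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2, s3),
        writeable=False,
    )
    return windows.reshape(B, C * k * k, H * W)


def _conv2d_raw(x, w, b, dilation, groups):
    """Forward-only grouped stride-1 same-padded conv on raw arrays."""
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    if kh != kw or kh % 2 == 0:
        raise ValueError("conv2d requires odd square kernels")
    k = kh
    if C % groups or Cout % groups or Cg * groups != C:
        raise ValueError(
            f"channel/group mismatch: input {C} channels, weight expects "
            f"{Cg * groups} ({groups} groups x {Cg})"
        )
    pad = dilation * (k - 1) // 2
    cols = _im2col(x, k, dilation, pad).reshape(B, groups, Cg * k * k, H * W)
    wr = w.reshape(groups, Cout // groups, Cg * k * k)
    out = np.matmul(wr[None], cols)  # [B, G, Cout/G, HW]
    out = out.reshape(B, Cout, H, W)
    if b is not None:
        out = out + b.reshape(1, Cout, 1, 1)
    if _mac_counter is not None:
        _mac_counter[0] += Cout * H * W * Cg * k * k * B
    return out, cols


def conv2d(x, w, b=None, *, dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 same-padded 2-D convolution (cross-correlation).

    ``groups=1`` is a standard conv, ``groups == channels`` a depthwise conv,
    ``k=1`` a pointwise conv; ``dilation`` inflates the receptive field.
    """
    x, w = _wrap(x), _wrap(w)
    b_t = _wrap(b) if b is not None else None
    out_data, cols = _conv2d_raw(
        x.data, w.data, None if b_t is None else b_t.data, dilation, groups
    )
    if not _grad_enabled:
        return Tensor(out_data)
    B, C, H, W = x.data.shape
    Cout, Cg, k, _ = w.data.shape
    parents = (x, w) + ((b_t,) if b_t is not None else ())

    def backward(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            gr = g.reshape(B, groups, Cout // groups, H * W)
            # [G, Cout/G, Cg*k*k] accumulated over batch
            dw = np.matmul(gr, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            _accum(w, dw.reshape(w.data.shape))
        if b_t is not None and b_t.requires_grad:
            _accum(b_t, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # transpose conv == same-padded conv with the flipped kernel
            wt = (
                w.data.reshape(groups, Cout // groups, Cg, k, k)
                .transpose(0, 2, 1, 3, 4)
                .reshape(C, Cout // groups, k, k)[:, :, ::-1, ::-1]
            )
            dx, _ = _conv2d_raw(g, np.ascontiguousarray(wt), None, dilation, groups)
            _accum(x, dx)

    return _make(out_data, parents, backward)


def conv1d_channels(s, w, b=None) -> Tensor:
    """1-D conv of a per-sample channel descriptor ``s`` of shape [B, C].

    Single input/output channel, odd kernel ``w`` of shape [k], "same" zero
    padding over the channel axis — the efficient-channel-attention operator.
    """
    s, w = _wrap(s), _wrap(w)
    b_t = _wrap(b) if b is not None else None
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError(f"1-D channel conv kernel length must be odd, got {k}")
    pad = (k - 1) // 2
    B, C = s.data.shape
    sp = np.pad(s.data, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(sp, k, axis=1)  # [B, C, k]
    out = win @ w.data
    if b_t is not None:
        out = out + b_t.data
    if _mac_counter is not None:
        _mac_counter[0] += B * C * k
    if not _grad_enabled:
        return Tensor(out)
    parents = (s, w) + ((b_t,) if b_t is not None else ())

    def backward(g):
        if w.requires_grad:
            _accum(w, np.einsum("bck,bc->k", win, g))
        if b_t is not None and b_t.requires_grad:
            _accum(b_t, g.sum())
        if s.requires_grad:
            gp = np.pad(g, ((0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
            _accum(s, gwin @ w.data[::-1])

    return _make(out, parents, backward)


def conv_transpose2d_2x(x, w, b=None) -> Tensor:
    """2x2 stride-2 transposed convolution: doubles H and W.

    Weight shape [Cin, Cout, 2, 2]; each input pixel paints one 2x2 block.
    """
    x, w = _wrap(x), _wrap(w)
    b_t = _wrap(b) if b is not None else None
    B, Ci, H, W = x.data.shape
    Ci2, Co, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"transposed conv expects {Ci2} input channels, got {Ci}")
    t = np.einsum("bihw,iokl->bohkwl", x.data, w.data, optimize=True)
    out = t.reshape(B, Co, 2 * H, 2 * W)
    if b_t is not None:
        out = out + b_t.data.reshape(1, Co, 1, 1)
    if _mac_counter is not None:
        _mac_counter[0] += B * Co * H * W * Ci * 4
    if not _grad_enabled:
        return Tensor(out)
    parents = (x, w) + ((b_t,) if b_t is not None else ())

    def backward(g):
        gt = g.reshape(B, Co, H, 2, W, 2)
        if x.requires_grad:
            _accum(x, np.einsum("bohkwl,iokl->bihw", gt, w.data, optimize=True))
        if w.requires_grad:
            _accum(w, np.einsum("bihw,bohkwl->iokl", x.data, gt, optimize=True))
        if b_t is not None and b_t.requires_grad:
            _accum(b_t, g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def max_pool2d(x) -> Tensor:
    """2x2 max pooling with stride 2 (even H and W required)."""
    x = _wrap(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"2x2 max pool needs even spatial extent, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    if not _grad_enabled:
        return Tensor(out)

    def backward(g):
        if x.requires_grad:
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            _accum(x, dx.reshape(B, C, H, W))

    return _make(out, (x,), backward)


def max_pool_same(x, k: int = 3) -> Tensor:
    """k x k max pooling, stride 1, same padding (saliency pooling)."""
    x = _wrap(x)
    if k % 2 == 0:
        raise ValueError("stride-1 same-padded max pool needs an odd window")
    pad = (k - 1) // 2
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, H, W, k, k), strides=(s0, s1, s2, s3, s2, s3),
        writeable=False,
    ).reshape(B, C, H, W, k * k)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    if not _grad_enabled:
        return Tensor(out)

    def backward(g):
        if x.requires_grad:
            onehot = np.zeros((B, C, H, W, k * k), dtype=g.dtype)
            np.put_along_axis(onehot, idx[..., None], g[..., None], axis=-1)
            dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + H, j : j + W] += onehot[..., i * k + j]
            _accum(x, dxp[:, :, pad : pad + H, pad : pad + W])

    return _make(out, (x,), backward)


def avg_pool2d(x, factor: int) -> Tensor:
    """factor x factor average pooling with stride = factor."""
    x = _wrap(x)
    if factor == 1:
        return x * 1.0 if x.requires_grad else x
    B, C, H, W = x.data.shape
    f = factor
    if H % f or W % f:
        raise ValueError(f"average pool factor {f} does not divide {H}x{W}")
    out = x.data.reshape(B, C, H // f, f, W // f, f).mean(axis=(3, 5))
    if not _grad_enabled:
        return Tensor(out)

    def backward(g):
        if x.requires_grad:
            dx = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
            _accum(x, dx)

    return _make(out, (x,), backward)


@lru_cache(maxsize=64)
def _bilinear_matrix(n_in: int) -> np.ndarray:
    """[2n, n] interpolation matrix for 2x bilinear upsampling (half-pixel)."""
    n_out = 2 * n_in
    M = np.zeros((n_out, n_in))
    for o in range(n_out):
        src = (o + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        M[o, i0c] += 1.0 - t
        M[o, i1c] += t
    return M


def upsample_bilinear_2x(x) -> Tensor:
    x = _wrap(x)
    B, C, H, W = x.data.shape
    Mh = _bilinear_matrix(H).astype(x.data.dtype)
    Mw = _bilinear_matrix(W).astype(x.data.dtype)
    out = np.einsum("oh,bchw,pw->bcop", Mh, x.data, Mw, optimize=True)
    if not _grad_enabled:
        return Tensor(out)

    def backward(g):
        if x.requires_grad:
            _accum(x, np.einsum("oh,bcop,pw->bchw", Mh, g, Mw, optimize=True))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(x, gamma, beta, running_mean, running_var, *,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over a [B, C, H, W] tensor.

    ``running_mean``/``running_var`` are plain numpy buffers updated in place
    during training and used verbatim in eval mode.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    B, C, H, W = x.data.shape
    n = B * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased running variance, biased batch variance for normalization
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    mu = mu.astype(x.data.dtype, copy=False)
    invstd = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype, copy=False)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * invstd.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)
    if not _grad_enabled:
        return Tensor(out)

    def backward(g):
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, C, 1, 1)
            if training:
                sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gxhat - sum_g / n - xhat * sum_gx / n) * invstd.reshape(
                    1, C, 1, 1
                )
            else:
                dx = gxhat * invstd.reshape(1, C, 1, 1)
            _accum(x, dx)

    return _make(out, (x, gamma, beta), backward)
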