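"""Convolution, pooling and activation functions on :class:`~moo_reid.nn.Tensor`.

2-D convolution is computed tap-by-tap: for each of the ``kh*kw`` kernel
positions a strided slice of the (padded) input is contracted against the
corresponding kernel column.  For the small kernels used here (1x1 .. 7x7)
this is both memory-light and fast, and the backward pass is the same loop
with scatter-adds, so gradients are exact.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample_nearest",
    "softmax",
    "pairwise_sqdist",
]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(x, weight, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """Grouped dilated 2-D cross-correlation.

    Parameters
    ----------
    x : Tensor, shape (B, C_in, H, W)
    weight : Tensor, shape (C_out, C_in // groups, kh, kw)
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = weight.shape
    if Cin != Cg * groups:
        raise ValueError(
            f"channel mismatch: input has {Cin} channels, "
            f"weight expects {Cg * groups} (groups={groups})"
        )
    Ho = (H + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    Wo = (W + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"kernel does not fit input of size {H}x{W}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    G, Cog = groups, Cout // groups
    Cg = Cin // G
    w = weight.data
    L = Ho * Wo
    depthwise = G == Cin and Cg == 1 and Cog == 1

    def tap(arr, i, j):
        return arr[
            ...,
            i * dh : i * dh + sh * (Ho - 1) + 1 : sh,
            j * dw : j * dw + sw * (Wo - 1) + 1 : sw,
        ]

    if depthwise:
        out = np.zeros((B, Cout, Ho, Wo), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                out += w[None, :, 0, i, j, None, None] * tap(xp, i, j)
    elif G == 1:
        out = np.zeros((B, Cout, L), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                out += w[:, :, i, j] @ tap(xp, i, j).reshape(B, Cin, L)
        out = out.reshape(B, Cout, Ho, Wo)
    else:
        xg = xp.reshape(B, G, Cg, *xp.shape[2:])
        wg = w.reshape(G, Cog, Cg, kh, kw)
        out = np.zeros((B, G, Cog, Ho, Wo), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                out += np.einsum("bgchw,goc->bgohw", tap(xg, i, j), wg[:, :, :, i, j])
        out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def backward(g):
        if weight.requires_grad:
            dw_ = np.zeros_like(w)
            if depthwise:
                for i in range(kh):
                    for j in range(kw):
                        dw_[:, 0, i, j] = (g * tap(xp, i, j)).sum(axis=(0, 2, 3))
            elif G == 1:
                gl = g.reshape(B, Cout, L)
                for i in range(kh):
                    for j in range(kw):
                        dw_[:, :, i, j] = np.tensordot(
                            gl, tap(xp, i, j).reshape(B, Cin, L), axes=([0, 2], [0, 2])
                        )
            else:
                gg = g.reshape(B, G, Cog, Ho, Wo)
                xg = xp.reshape(B, G, Cg, *xp.shape[2:])
                dwg = dw_.reshape(G, Cog, Cg, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        dwg[:, :, :, i, j] = np.einsum(
                            "bgohw,bgchw->goc", gg, tap(xg, i, j)
                        )
            weight._accumulate(dw_)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            if depthwise:
                for i in range(kh):
                    for j in range(kw):
                        tap(dxp, i, j)[...] += w[None, :, 0, i, j, None, None] * g
            elif G == 1:
                gl = g.reshape(B, Cout, L)
                for i in range(kh):
                    for j in range(kw):
                        tap(dxp, i, j)[...] += (w[:, :, i, j].T @ gl).reshape(
                            B, Cin, Ho, Wo
                        )
            else:
                gg = g.reshape(B, G, Cog, Ho, Wo)
                dxg = dxp.reshape(B, G, Cg, *dxp.shape[2:])
                wg = w.reshape(G, Cog, Cg, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        tap(dxg, i, j)[...] += np.einsum(
                            "bgohw,goc->bgchw", gg, wg[:, :, :, i, j]
                        )
            if ph or pw:
                dxp = dxp[:, :, ph : ph + H, pw : pw + W]
            x._accumulate(np.ascontiguousarray(dxp))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor.from_op(out, parents, backward)


def max_pool2d(x, kernel_size=3, stride=2, padding=1):
    x = as_tensor(x)
    kh, kw = _pair(kernel_size)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)

    def tap_slice(i, j):
        return (
            slice(None),
            slice(None),
            slice(i, i + sh * (Ho - 1) + 1, sh),
            slice(j, j + sw * (Wo - 1) + 1, sw),
        )

    taps = np.stack([xp[tap_slice(i, j)] for i in range(kh) for j in range(kw)])
    arg = taps.argmax(axis=0)
    out = np.take_along_axis(taps, arg[None], axis=0)[0]

    def backward(g):
        dxp = np.zeros_like(xp)
        for t in range(kh * kw):
            i, j = divmod(t, kw)
            dxp[tap_slice(i, j)] += g * (arg == t)
        x._accumulate(dxp[:, :, ph : ph + H, pw : pw + W])

    return Tensor.from_op(out, (x,), backward)


def avg_pool2d(x, kernel_size):
    """Non-overlapping average pooling (stride = kernel size)."""
    x = as_tensor(x)
    kh, kw = _pair(kernel_size)
    B, C, H, W = x.shape
    if H % kh or W % kw:
        raise ValueError(f"spatial size {H}x{W} not divisible by pool {kh}x{kw}")
    y = x.reshape(B, C, H // kh, kh, W // kw, kw)
    return y.mean(axis=(3, 5))


def upsample_nearest(x, scale):
    x = as_tensor(x)
    s = int(scale)
    B, C, H, W = x.shape
    out = x.data.repeat(s, axis=2).repeat(s, axis=3)

    def backward(g):
        x._accumulate(g.reshape(B, C, H, s, W, s).sum(axis=(3, 5)))

    return Tensor.from_op(out, (x,), backward)


def softmax(x, axis=-1):
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def pairwise_sqdist(a, b):
    """Squared Euclidean distances between row sets: (n, d) x (m, d) -> (n, m)."""
    a, b = as_tensor(a), as_tensor(b)
    a2 = (a * a).sum(axis=1, keepdims=True)
    b2 = (b * b).sum(axis=1, keepdims=True)
    cross = a @ b.transpose(1, 0)
    return (a2 + b2.transpose(1, 0) - 2.0 * cross).clamp_min(0.0)
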