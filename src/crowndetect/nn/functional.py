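"""Convolution, pooling and upsampling primitives for the tensor engine.

Convolutions are computed by extracting sliding windows
(`numpy.lib.stride_tricks.sliding_window_view`) and contracting with
`numpy.einsum`; the input gradient is scattered back with one vectorised
add per kernel tap, so even the 1x10 / 10x1 strip kernels stay cheap.

Padding is given per side as ((top, bottom), (left, right)); this matters
because the strip kernels have even length, where "same" padding is
necessarily asymmetric.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "avg_pool2d", "upsample_nearest2d", "same_padding"]


def _conv1x1(x: Tensor, weight: Tensor, bias, stride: int) -> Tensor:
    """Pointwise convolution as a channel matmul (no window extraction)."""
    xs = x.data if stride == 1 else np.ascontiguousarray(x.data[:, :, ::stride, ::stride])
    B, C, Ho, Wo = xs.shape
    w2 = weight.data[:, :, 0, 0]                       # (Cout, C)
    out = np.einsum("oc,bchw->bohw", w2, xs, optimize=True)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out, dtype=x.data.dtype)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
            weight._accum(gw[:, :, None, None].astype(weight.data.dtype))
        if x.requires_grad:
            dxs = np.einsum("bohw,oc->bchw", g, w2, optimize=True)
            if stride == 1:
                x._accum(dxs)
            else:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
                x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._wrap(out, parents, backward)


def same_padding(k: int) -> tuple:
    """Per-side padding preserving length under stride 1.

    For even k the split is asymmetric: floor((k-1)/2) leading,
    ceil((k-1)/2) trailing.
    """
    return ((k - 1) // 2, k // 2)


def _pad_input(x: np.ndarray, pad_h, pad_w) -> np.ndarray:
    if pad_h == (0, 0) and pad_w == (0, 0):
        return x
    return np.pad(x, ((0, 0), (0, 0), pad_h, pad_w))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding=((0, 0), (0, 0)), groups: int = 1) -> Tensor:
    """2-D cross-correlation.

    x: (B, C, H, W); weight: (Cout, C // groups, kh, kw).
    Supports groups == 1 (dense) and groups == C with Cout == C (depthwise);
    these are the only two patterns the network uses.
    """
    B, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    pad_h, pad_w = padding

    if kh == 1 and kw == 1 and groups == 1 and pad_h == (0, 0) and pad_w == (0, 0):
        return _conv1x1(x, weight, bias, stride)

    xp = _pad_input(x.data, pad_h, pad_w)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    depthwise = groups == C and Cout == C and Cin_g == 1
    if not depthwise and groups != 1:
        raise NotImplementedError("conv2d supports groups=1 or depthwise only")

    def taps():
        for i in range(kh):
            for j in range(kw):
                yield i, j, xp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride]

    if depthwise:
        # shift-and-add over the <= k*k kernel taps; no window buffers
        out = np.zeros((B, C, Ho, Wo), dtype=x.data.dtype)
        for i, j, xs in taps():
            out += xs * weight.data[:, 0, i, j][None, :, None, None]
    else:
        acc = np.zeros((B, Ho, Wo, Cout), dtype=x.data.dtype)
        for i, j, xs in taps():
            acc += np.tensordot(xs, weight.data[:, :, i, j], axes=(1, 1))
        out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out, dtype=x.data.dtype)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        dxp = np.zeros((B, C, Hp, Wp), dtype=x.data.dtype) if need_dx else None
        if depthwise:
            if weight.requires_grad and weight.grad is None:
                weight.grad = np.zeros_like(weight.data)
            for i, j, xs in taps():
                if weight.requires_grad:
                    weight.grad[:, 0, i, j] += np.einsum("bchw,bchw->c", xs, g,
                                                         optimize=True)
                if need_dx:
                    dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        g * weight.data[:, 0, i, j][None, :, None, None]
        else:
            gT = np.ascontiguousarray(g.transpose(0, 2, 3, 1))   # (B, Ho, Wo, Cout)
            for i, j, xs in taps():
                if weight.requires_grad:
                    gw = np.tensordot(gT, xs, axes=([0, 1, 2], [0, 2, 3]))
                    weight.grad = weight.grad if weight.grad is not None else np.zeros_like(weight.data)
                    weight.grad[:, :, i, j] += gw.astype(weight.data.dtype)
                if need_dx:
                    dxs = np.tensordot(gT, weight.data[:, :, i, j], axes=(3, 0))
                    dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        dxs.transpose(0, 3, 1, 2)
        if need_dx:
            x._accum(dxp[:, :, pad_h[0]:Hp - pad_h[1] or None, pad_w[0]:Wp - pad_w[1] or None])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._wrap(out, parents, backward)


def avg_pool2d(x: Tensor, k: int, *, stride: int = 1) -> Tensor:
    """Local average pooling with "same"-style symmetric padding (k odd).

    Stride-1 with padding (k-1)/2 preserves the spatial shape; averaging
    always divides by k*k (zero padding contributes zeros), matching the
    usual count_include_pad convention.
    """
    if k % 2 != 1:
        raise ValueError("avg_pool2d expects an odd window")
    p = (k - 1) // 2
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = cols.mean(axis=(4, 5)).astype(x.data.dtype)
    Ho, Wo = out.shape[2], out.shape[3]

    def backward(g):
        if not x.requires_grad:
            return
        gsc = g / (k * k)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += gsc
        x._accum(dxp[:, :, p:p + H, p:p + W])

    return Tensor._wrap(out, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        B, C, H, W = x.data.shape
        x._accum(g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5)))

    return Tensor._wrap(out, (x,), backward)
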