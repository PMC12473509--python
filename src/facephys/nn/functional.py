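"""Convolution and pooling primitives with custom backward passes.

Convolutions use an im2col + GEMM strategy; all are "valid" (no implicit
padding) with stride 1, matching the small fixed-size crops the embeddings
operate on.  The depthwise causal 1-D convolution is the temporal mixer used
inside the selective state-space block.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv1d",
    "depthwise_causal_conv1d",
    "avg_pool2d",
    "adaptive_avg_pool2d",
]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Valid 2-D convolution (cross-correlation).  x: (B,Cin,H,W), weight:
    (Cout,Cin,kh,kw) -> (B,Cout,H-kh+1,W-kw+1)."""
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    Ho, Wo = H - kh + 1, W - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("input smaller than kernel")
    # (B, Cin, Ho, Wo, kh, kw) view -> (B*Ho*Wo, Cin*kh*kw) copy
    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, Cin * kh * kw
    )
    wmat = weight.data.reshape(Cout, Cin * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, Cin, kh, kw)
            dx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            x._accumulate(dx)

    return Tensor._make(out, parents, backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Valid 1-D convolution.  x: (B,Cin,P), weight: (Cout,Cin,k)."""
    B, Cin, P = x.shape
    Cout, Cin_w, k = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    Po = P - k + 1
    if Po < 1:
        raise ValueError("input shorter than kernel")
    win = sliding_window_view(x.data, k, axis=2)  # (B, Cin, Po, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Po, Cin * k)
    wmat = weight.data.reshape(Cout, Cin * k)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(B, Po, Cout).transpose(0, 2, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Po, Cout)
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Po, Cin, k)
            dx = np.zeros_like(x.data)
            for j in range(k):
                dx[:, :, j : j + Po] += dcols[:, :, :, j].transpose(0, 2, 1)
            x._accumulate(dx)

    return Tensor._make(out, parents, backward)


def depthwise_causal_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Per-channel causal 1-D convolution.  x: (B,C,L), weight: (C,k).

    Output at time t depends on x[..., t-k+1 .. t]; the sequence is left-padded
    with zeros so the shape is preserved.
    """
    B, C, L = x.shape
    C_w, k = weight.shape
    if C != C_w:
        raise ValueError("channel mismatch in depthwise conv")
    xpad = np.pad(x.data, ((0, 0), (0, 0), (k - 1, 0)))
    win = sliding_window_view(xpad, k, axis=2)  # (B, C, L, k)
    out = np.einsum("bclk,ck->bcl", win, weight.data, optimize=True)
    if bias is not None:
        out += bias.data[None, :, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("bcl,bclk->ck", g, win, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxpad = np.zeros_like(xpad)
            for j in range(k):
                dxpad[:, :, j : j + L] += g * weight.data[None, :, j, None]
            x._accumulate(dxpad[:, :, k - 1 :])

    return Tensor._make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k average pooling (floor division; edges dropped)."""
    B, C, H, W = x.shape
    Ho, Wo = H // k, W // k
    if Ho < 1 or Wo < 1:
        raise ValueError("input smaller than pooling window")
    xc = x.data[:, :, : Ho * k, : Wo * k]
    out = xc.reshape(B, C, Ho, k, Wo, k).mean(axis=(3, 5))

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * k, : Wo * k] = np.repeat(
            np.repeat(g, k, axis=2), k, axis=3
        ) / (k * k)
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)


def _adaptive_bins(n_in: int, n_out: int):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)  # ceil
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive average pooling over the last two axes of (B,C,H,W)."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    hs, he = _adaptive_bins(H, Ho)
    ws, we = _adaptive_bins(W, Wo)
    out = np.empty((B, C, Ho, Wo), dtype=x.dtype)
    for i in range(Ho):
        row = x.data[:, :, hs[i] : he[i], :]
        for j in range(Wo):
            out[:, :, i, j] = row[:, :, :, ws[j] : we[j]].mean(axis=(2, 3))

    def backward(g):
        dx = np.zeros_like(x.data)
        for i in range(Ho):
            for j in range(Wo):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i] : he[i], ws[j] : we[j]] += (
                    g[:, :, i, j][:, :, None, None] / area
                )
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)
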