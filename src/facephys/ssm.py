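"""State-space primitives: ZOH discretization, recurrent scan, and the
convolution-equivalent LTI path.

These are plain-numpy reference operations, kept in float64 and independent
of the learned encoder so the recurrence and the convolution form can be
checked against each other exactly.  The continuous system

    h'(t) = A h(t) + B x(t),      y(t) = C h(t) + D x(t)

with diagonal ``A`` (entries strictly negative) is discretized under a
zero-order hold:  Abar = exp(A*delta), Bbar = (Abar - 1)/A * B, which is the
exact integral of exp(A*tau)*B over one sampling interval for diagonal A.
In LTI mode the recurrence equals a causal convolution with kernel
K_t = C Abar^t Bbar.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "discretize_zoh",
    "ssm_scan",
    "ssm_conv_kernel",
    "ssm_conv_apply",
]


def discretize_zoh(A: np.ndarray, B: np.ndarray, delta) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a diagonal continuous-time SSM under zero-order hold.

    Parameters
    ----------
    A : array of diagonal state-matrix entries (any shape, all < 0 for a
        stable system; zeros are rejected).
    B : input projection, broadcastable against ``A``.
    delta : positive sampling interval(s), broadcastable against ``A``.

    Returns
    -------
    (A_bar, B_bar) with ``A_bar = exp(A*delta)`` and the exact ZOH integral
    ``B_bar = (A_bar - 1)/A * B``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be strictly positive")
    if np.any(A == 0):
        raise ValueError("diagonal entries of A must be nonzero")
    A_bar = np.exp(A * delta)
    B_bar = (A_bar - 1.0) / A * B
    return A_bar, np.broadcast_arrays(B_bar, A_bar)[0].copy()


def ssm_scan(
    x: np.ndarray,
    A_bar: np.ndarray,
    B_bar: np.ndarray,
    C: np.ndarray,
    D_skip=0.0,
    h0: np.ndarray | None = None,
) -> np.ndarray:
    """Run the discrete recurrence  h_k = A_bar h_{k-1} + B_bar x_k,
    y_k = C h_k + D x_k.

    Shapes: x (L, ch); A_bar, B_bar, C (ch, N); D_skip scalar or (ch,);
    h0 optional (ch, N), default zero.  Returns y (L, ch).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("input sequence contains non-finite values")
    A_bar = np.atleast_2d(np.asarray(A_bar, dtype=float))
    B_bar = np.atleast_2d(np.asarray(B_bar, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    L, ch = x.shape
    h = np.zeros_like(A_bar) if h0 is None else np.array(h0, dtype=float)
    y = np.empty((L, ch))
    for k in range(L):
        h = A_bar * h + B_bar * x[k][:, None]
        y[k] = (C * h).sum(axis=1)
    return y + np.asarray(D_skip, dtype=float) * x


def ssm_conv_kernel(A_bar: np.ndarray, B_bar: np.ndarray, C: np.ndarray, L: int) -> np.ndarray:
    """LTI impulse-response kernel K_t = C A_bar^t B_bar for t = 0..L-1.

    Only defined for input-independent (time-invariant) parameters; returns
    shape (L, ch) for per-channel diagonal systems.
    """
    if L < 1:
        raise ValueError("kernel length must be >= 1")
    A_bar = np.atleast_2d(np.asarray(A_bar, dtype=float))
    B_bar = np.atleast_2d(np.asarray(B_bar, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    t = np.arange(L)[:, None, None]
    powers = A_bar[None, :, :] ** t  # (L, ch, N)
    return (C[None] * powers * B_bar[None]).sum(axis=2)


def ssm_conv_apply(x: np.ndarray, K: np.ndarray, D_skip=0.0) -> np.ndarray:
    """Causal convolution  y_k = sum_{t<=k} K_t x_{k-t} + D x_k.

    x: (L, ch) or (L,); K: (Lk, ch) with Lk >= L (extra tail ignored).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    K = np.asarray(K, dtype=float)
    if K.ndim == 1:
        K = K[:, None]
    L, ch = x.shape
    if K.shape[0] < L:
        raise ValueError("kernel shorter than input")
    y = np.empty((L, ch))
    for c in range(ch):
        y[:, c] = np.convolve(x[:, c], K[:L, c])[:L]
    y += np.asarray(D_skip, dtype=float) * x
    return y[:, 0] if squeeze else y
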