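"""Selective state-space (Mamba-style) block and the bidirectional encoder.

Each block follows the canonical selective-SSM recipe: pre-normalization,
input projection to an expanded width, a depthwise *causal* 1-D convolution,
SiLU, a selective scan whose step size delta and projections B, C are
computed from the current input, a multiplicative SiLU gate, an output
projection, and a residual connection.  The state matrix is diagonal with
strictly negative entries, A = -exp(A_log), so every discretized transition
factor exp(A*delta) lies in (0, 1) and the recurrence is unconditionally
stable.

The bidirectional encoder runs two independent stacks — one over the input
sequence, one over its time reversal (re-reversed afterwards so both outputs
share the forward time axis) — maps each through its own linear layer, and
concatenates them along the feature axis.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["RMSNorm", "MambaBlock", "BidirectionalEncoder"]


class RMSNorm(nn.Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=-1, keepdims=True)
        return x * ((ms + self.eps) ** -0.5) * self.gamma


class MambaBlock(nn.Module):
    """One residual selective-SSM block operating on (batch, L, D) sequences.

    Parameters
    ----------
    d_model : feature width D (preserved by the block).
    state_dim : per-channel diagonal state size N.
    expand : inner-width multiplier (E = expand * D).
    conv_kernel : depthwise causal convolution width.
    dt_min, dt_max : initialization range for the softplus-ed step size.
    exact_zoh : use the exact diagonal ZOH integral for Bbar (default) or
        the Euler simplification delta*B.
    """

    def __init__(
        self,
        d_model: int,
        rng: np.random.Generator,
        state_dim: int = 16,
        expand: int = 2,
        conv_kernel: int = 4,
        dt_rank: int | None = None,
        dt_min: float = 1e-3,
        dt_max: float = 1e-1,
        exact_zoh: bool = True,
    ):
        super().__init__()
        D = d_model
        E = expand * d_model
        R = dt_rank if dt_rank is not None else max(1, math.ceil(D / 16))
        self.d_model, self.d_inner, self.state_dim, self.dt_rank = D, E, state_dim, R
        self.exact_zoh = exact_zoh

        self.norm = RMSNorm(D)
        self.in_proj = nn.Linear(D, 2 * E, rng, bias=False)
        self.conv = nn.DepthwiseCausalConv1d(E, conv_kernel, rng)
        self.x_proj = nn.Linear(E, R + 2 * state_dim, rng, bias=False)
        self.dt_proj = nn.Linear(R, E, rng, bias=True)
        # bias init so that softplus(bias) lands in [dt_min, dt_max]
        dt = np.exp(
            rng.uniform(math.log(dt_min), math.log(dt_max), size=E)
        ).astype(np.float32)
        self.dt_proj.bias.data = (dt + np.log(-np.expm1(-dt))).astype(np.float32)
        # A_log init: A_n = -n for n = 1..N, replicated per inner channel
        self.A_log = Tensor(
            np.log(np.tile(np.arange(1, state_dim + 1, dtype=np.float32), (E, 1))),
            requires_grad=True,
        )
        self.D_skip = Tensor(np.ones(E, dtype=np.float32), requires_grad=True)
        self.out_proj = nn.Linear(E, D, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_model:
            raise ValueError(
                f"expected feature width {self.d_model}, got {x.shape[-1]}"
            )
        u = self.norm(x)
        xz = self.in_proj(u)  # (B, L, 2E)
        E = self.d_inner
        xs, z = xz[:, :, :E], xz[:, :, E:]
        xs = self.conv(xs.transpose(0, 2, 1)).transpose(0, 2, 1).silu()
        proj = self.x_proj(xs)  # (B, L, R + 2N)
        R, N = self.dt_rank, self.state_dim
        delta = (self.dt_proj(proj[:, :, :R]).softplus()) + 1e-6
        Bmat = proj[:, :, R : R + N]
        Cmat = proj[:, :, R + N :]
        A = -self.A_log.exp()
        y = nn.selective_scan(
            xs, delta, A, Bmat, Cmat, self.D_skip, exact_zoh=self.exact_zoh
        )
        y = y * z.silu()
        return x + self.out_proj(y)


class BidirectionalEncoder(nn.Module):
    """Forward and backward selective-SSM stacks with independent parameters.

    Output is H_bi of shape (batch, L, 2*d_out): columns [0, d_out) come from
    the forward branch, [d_out, 2*d_out) from the backward branch, both on
    the forward time axis.
    """

    def __init__(
        self,
        d_model: int,
        rng: np.random.Generator,
        depth: int = 3,
        d_out: int | None = None,
        **block_kwargs,
    ):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.d_model = d_model
        self.d_out = d_out if d_out is not None else d_model
        self.forward_blocks = [
            MambaBlock(d_model, rng, **block_kwargs) for _ in range(depth)
        ]
        self.backward_blocks = [
            MambaBlock(d_model, rng, **block_kwargs) for _ in range(depth)
        ]
        self.forward_out = nn.Linear(d_model, self.d_out, rng)
        self.backward_out = nn.Linear(d_model, self.d_out, rng)

    def forward(self, F: Tensor) -> Tensor:
        hf = F
        for blk in self.forward_blocks:
            hf = blk(hf)
        hb = F.flip(1)
        for blk in self.backward_blocks:
            hb = blk(hb)
        hb = hb.flip(1)  # re-align the backward branch to forward time order
        zf = self.forward_out(hf)
        zb = self.backward_out(hb)
        return nn.concat([zf, zb], axis=-1)
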