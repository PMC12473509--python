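"""Temporal fusion and the three task heads.

The encoder output H_bi (L x 2D'') is collapsed by plain average pooling
over time, h_fused = (1/L) sum_t H_bi(t), and fed to three independent
two-layer MLPs: unbounded scalar regressors for heart rate and respiration
rate, and a sigmoid-squashed binary head for cognitive load.  The heads
share no parameters — the network branches only at the prediction layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["Predictions", "mean_pool", "MLPHead", "PredictionHeads"]


@dataclass
class Predictions:
    hr_bpm: np.ndarray  # (B,)
    rr_rpm: np.ndarray  # (B,)
    cog_prob: np.ndarray  # (B,), strictly inside (0, 1)


def mean_pool(h_bi: Tensor) -> Tensor:
    """Average over the time axis of (B, L, C) -> (B, C)."""
    if h_bi.ndim != 3 or h_bi.shape[1] < 1:
        raise ValueError("mean_pool expects a non-empty (B, L, C) sequence")
    return h_bi.mean(axis=1)


class MLPHead(nn.Module):
    """Two-layer perceptron to a scalar."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).silu())[:, 0]


class PredictionHeads(nn.Module):
    def __init__(self, in_dim: int, rng: np.random.Generator, hidden: int = 128):
        super().__init__()
        self.hr = MLPHead(in_dim, hidden, rng)
        self.rr = MLPHead(in_dim, hidden, rng)
        self.cog = MLPHead(in_dim, hidden, rng)

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (hr_bpm, rr_rpm, cog_prob) tensors of shape (B,)."""
        if not np.all(np.isfinite(h.data)):
            raise ValueError("non-finite fused features")
        return self.hr(h), self.rr(h), self.cog(h).sigmoid()
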