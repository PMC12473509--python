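"""Task losses and the dynamic multi-task weight schedule.

Cognitive load uses a *truncated* cross-entropy: the per-sample loss is
-log max(p_y, eps), so samples whose true-label probability has fallen
below the floor eps contribute a constant -log(eps) and, crucially, zero
gradient — outliers and mislabeled windows cannot dominate the update.

Heart/respiration regression uses the smooth-L1 loss (quadratic within one
unit of error, linear outside).  The regression terms enter the total with
a shared weight lambda that ramps along a sigmoid in training progress:

    t = 2 * iter_current / iter_total,      lambda = 2 / (1 + exp(-10 t))

so lambda(0) = 1 and lambda -> 2 as training ends.  The formula is applied
as printed; an optional variant (``start_zero``) subtracts 1 so the ramp
starts at 0 for users who want the regression tasks silent at the start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossBundle",
    "truncated_ce",
    "smooth_l1",
    "lambda_schedule",
    "total_loss",
]


@dataclass
class LossBundle:
    L_cog: float
    L_hr: float
    L_rr: float
    lam: float
    t: float
    L_total: float


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def truncated_ce(p: Tensor | np.ndarray, y: np.ndarray, epsilon: float = 0.01) -> Tensor:
    """Mean truncated cross-entropy over a batch.

    p: predicted probability of the positive class, in [0, 1]; y: labels in
    {0, 1}.  With p_y = p if y=1 else 1-p, the loss is -log(max(p_y, eps)):
    capped at -log(eps), with zero gradient wherever p_y < eps.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    p = _as_tensor(p)
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    p_y = p * y + (1.0 - p) * (1.0 - y)
    return -(p_y.maximum(epsilon).log()).mean()


def smooth_l1(pred: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Mean smooth-L1: 0.5 e^2 for |e| < 1, |e| - 0.5 otherwise."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=float)
    e = (pred - target).abs()
    # min(e, 1) * (e - 0.5*min(e, 1)) equals both branches and is smooth at 1
    capped = -((-e).maximum(-1.0))
    return (capped * (e - 0.5 * capped)).mean()


def lambda_schedule(iter_current: int, iter_total: int, start_zero: bool = False) -> tuple[float, float]:
    """Return (t, lambda) of the sigmoid ramp."""
    if iter_total <= 0:
        raise ValueError("iter_total must be positive")
    if not (0 <= iter_current <= iter_total):
        raise ValueError("iter_current must lie in [0, iter_total]")
    t = 2.0 * iter_current / iter_total
    lam = 2.0 / (1.0 + np.exp(-10.0 * t))
    if start_zero:
        lam -= 1.0
    return t, float(lam)


def total_loss(
    L_cog: Tensor | float,
    L_hr: Tensor | float,
    L_rr: Tensor | float,
    lam: float,
    t: float = float("nan"),
) -> tuple[Tensor, LossBundle]:
    """Compose L_total = L_cog + lambda*(L_hr + L_rr)."""
    Lc, Lh, Lr = _as_tensor(L_cog), _as_tensor(L_hr), _as_tensor(L_rr)
    total = Lc + lam * Lh + lam * Lr
    bundle = LossBundle(
        L_cog=float(Lc.data), L_hr=float(Lh.data), L_rr=float(Lr.data),
        lam=float(lam), t=float(t), L_total=float(total.data),
    )
    return total, bundle
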