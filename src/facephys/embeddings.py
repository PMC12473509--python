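"""Branch embeddings: five inputs -> five temporally aligned (L, d) sequences.

Branches (in the fixed concatenation order): left eye, right eye and mouth
clips through a shared-architecture convolutional encoder with a temporal
shift module in front; the 106-point landmark sequence through a 1-D
convolutional encoder over the point axis; and the STMap through a 2-D
convolutional encoder whose spatial axis is collapsed by adaptive average
pooling while the time axis is resampled to L.  All branches produce the
same L with no interpolation, so concatenation along the feature axis gives
F of shape (L, 5*d).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F
from .preprocessing import REGION_SHAPES, SubregionClip

__all__ = [
    "BRANCH_ORDER",
    "wtsm",
    "wtsm_tensor",
    "SubregionEmbedding",
    "LandmarkEmbedding",
    "STMapEmbedding",
    "concat_features",
]

BRANCH_ORDER = ("left_eye", "right_eye", "mouth", "facial", "stmap")


def wtsm_tensor(x: Tensor, fold_div: int = 3) -> Tensor:
    """Temporal shift over channel groups of a clip tensor (B, L, C, H, W).

    The first C//fold_div channels are shifted one frame forward in time,
    the next C//fold_div one frame backward, the rest left in place; vacated
    frames are zero-filled.  The operation is linear and shape-preserving.
    It perturbs each frame with its neighbours before any spatial
    convolution, which is what makes the per-frame encoder temporally aware.
    """
    C = x.shape[2]
    fold = C // fold_div
    if fold < 1:
        raise ValueError(
            f"fold_div={fold_div} incompatible with {C} channels (empty shift group)"
        )
    g1 = x[:, :, :fold]
    g2 = x[:, :, fold : 2 * fold]
    g3 = x[:, :, 2 * fold :]
    # forward shift: frame t receives frame t-1; first frame becomes zero
    g1 = nn.pad_time(g1, 1, 0, axis=1)[:, :-1]
    # backward shift: frame t receives frame t+1; last frame becomes zero
    g2 = nn.pad_time(g2, 0, 1, axis=1)[:, 1:]
    return nn.concat([g1, g2, g3], axis=2)


def wtsm(clip: SubregionClip, fold_div: int = 3) -> SubregionClip:
    """Numpy-level temporal shift of a subregion clip (L, 3, h, w)."""
    shifted = wtsm_tensor(Tensor(clip.pixels[None]), fold_div=fold_div)
    return SubregionClip(region=clip.region, pixels=shifted.data[0])


class SubregionEmbedding(nn.Module):
    """Eye/mouth clip encoder: WTSM, two conv+pool stages, FC to d.

    Input (B, L, 3, h, w) with (h, w) fixed by the region; output (B, L, d).
    """

    def __init__(
        self,
        region: str,
        d: int,
        rng: np.random.Generator,
        c1: int = 16,
        c2: int = 32,
        fold_div: int = 3,
        use_wtsm: bool = True,
    ):
        super().__init__()
        if d <= 0:
            raise ValueError("feature dimension d must be positive")
        h, w = REGION_SHAPES[region]
        self.region = region
        self.fold_div = fold_div
        self.use_wtsm = use_wtsm
        self.conv1 = nn.Conv2d(3, c1, 3, rng)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng)
        h2, w2 = (h - 2) // 2, (w - 2) // 2
        h4, w4 = (h2 - 2) // 2, (w2 - 2) // 2
        self.flat_dim = c2 * h4 * w4
        self.fc = nn.Linear(self.flat_dim, d, rng)
        self.d = d

    def forward(self, clips: Tensor) -> Tensor:
        B, L = clips.shape[0], clips.shape[1]
        h, w = REGION_SHAPES[self.region]
        if clips.shape[2:] != (3, h, w):
            raise ValueError(
                f"{self.region} clip must be (B, L, 3, {h}, {w}), got {clips.shape}"
            )
        x = wtsm_tensor(clips, self.fold_div) if self.use_wtsm else clips
        x = x.reshape(B * L, 3, h, w)
        # activation after pooling: same nonlinearity budget, quarter the work
        x = F.avg_pool2d(self.conv1(x), 2).silu()
        x = F.avg_pool2d(self.conv2(x), 2).silu()
        x = x.reshape(B * L, self.flat_dim)
        return self.fc(x).reshape(B, L, self.d)


class LandmarkEmbedding(nn.Module):
    """Landmark encoder: 1-D conv over the 106 points with the (x, y)
    coordinates as channels, batch norm, SiLU, FC to d."""

    N_POINTS = 106

    def __init__(self, d: int, rng: np.random.Generator, channels: int = 16):
        super().__init__()
        if d <= 0:
            raise ValueError("feature dimension d must be positive")
        self.conv = nn.Conv1d(2, channels, 3, rng)
        self.bn = nn.BatchNorm1d(channels)
        self.flat_dim = channels * (self.N_POINTS - 2)
        self.fc = nn.Linear(self.flat_dim, d, rng)
        self.d = d

    def forward(self, lm: Tensor) -> Tensor:
        if lm.shape[2:] != (self.N_POINTS, 2):
            raise ValueError(f"landmarks must be (B, L, {self.N_POINTS}, 2), got {lm.shape}")
        B, L = lm.shape[0], lm.shape[1]
        x = lm.reshape(B * L, self.N_POINTS, 2).transpose(0, 2, 1)  # (BL, 2, 106)
        x = self.bn(self.conv(x)).silu()
        x = x.reshape(B * L, self.flat_dim)
        return self.fc(x).reshape(B, L, self.d)


class STMapEmbedding(nn.Module):
    """STMap encoder: two conv+BN+SiLU stages over the (H, L) image, then
    adaptive average pooling to (1, L) and reshape to (B, L, d).

    The time axis is resampled back to exactly L regardless of what the
    valid convolutions did to it.
    """

    def __init__(self, d: int, rng: np.random.Generator, c1: int = 16):
        super().__init__()
        if d <= 0:
            raise ValueError("feature dimension d must be positive")
        self.conv1 = nn.Conv2d(3, c1, 3, rng)
        self.bn1 = nn.BatchNorm2d(c1)
        self.conv2 = nn.Conv2d(c1, d, 3, rng)
        self.bn2 = nn.BatchNorm2d(d)
        self.d = d

    def forward(self, stmap: Tensor, L: int) -> Tensor:
        if stmap.ndim != 4 or stmap.shape[1] != 3:
            raise ValueError(f"stmap must be (B, 3, H, L), got {stmap.shape}")
        if stmap.shape[2] < 5:
            raise ValueError("STMap spatial axis smaller than the conv kernels")
        x = self.bn1(self.conv1(stmap)).silu()
        x = self.bn2(self.conv2(x)).silu()
        x = F.adaptive_avg_pool2d(x, (1, L))  # (B, d, 1, L)
        B = x.shape[0]
        return x.reshape(B, self.d, L).transpose(0, 2, 1)


def concat_features(branches: dict[str, Tensor]) -> Tensor:
    """Concatenate the five branch sequences along the feature axis.

    ``branches`` must contain exactly the keys in :data:`BRANCH_ORDER`, each
    of identical shape (B, L, d); the result is (B, L, 5*d) with column
    blocks in branch order.
    """
    missing = set(BRANCH_ORDER) - set(branches)
    extra = set(branches) - set(BRANCH_ORDER)
    if missing or extra:
        raise KeyError(f"branches must be exactly {BRANCH_ORDER}; missing={missing}, extra={extra}")
    shapes = {k: branches[k].shape for k in BRANCH_ORDER}
    first = shapes[BRANCH_ORDER[0]]
    if any(s != first for s in shapes.values()):
        raise ValueError(f"branch shapes must match, got {shapes}")
    return nn.concat([branches[k] for k in BRANCH_ORDER], axis=-1)
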