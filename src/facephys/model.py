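"""The full multi-task model: five embeddings, bidirectional selective
state-space encoder, mean pooling, three heads."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .config import ModelConfig
from .embeddings import (
    LandmarkEmbedding,
    STMapEmbedding,
    SubregionEmbedding,
    concat_features,
)
from .heads import PredictionHeads, mean_pool
from .mamba import BidirectionalEncoder

__all__ = ["MultiTaskModel", "save_checkpoint", "load_checkpoint"]


class MultiTaskModel(nn.Module):
    """End-to-end network from the five aligned inputs to the three outputs.

    Inputs (as a dict of Tensors or numpy arrays):
      left_eye, right_eye : (B, L, 3, 25, 25)
      mouth               : (B, L, 3, 15, 35)
      landmarks           : (B, L, 106, 2), normalized to [0, 1]
      stmap               : (B, 3, H, L)
    Outputs: (hr_bpm, rr_rpm, cog_prob) tensors of shape (B,).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        kw = dict(c1=config.subregion_c1, c2=config.subregion_c2,
                  fold_div=config.fold_div, use_wtsm=config.use_wtsm)
        self.embed_left_eye = SubregionEmbedding("left_eye", config.d, rng, **kw)
        self.embed_right_eye = SubregionEmbedding("right_eye", config.d, rng, **kw)
        self.embed_mouth = SubregionEmbedding("mouth", config.d, rng, **kw)
        self.embed_facial = LandmarkEmbedding(config.d, rng, channels=config.landmark_channels)
        self.embed_stmap = STMapEmbedding(config.d, rng, c1=config.stmap_c1)
        self.encoder = BidirectionalEncoder(
            config.D,
            rng,
            depth=config.depth,
            d_out=config.d_out_effective,
            state_dim=config.state_dim,
            expand=config.expand,
            conv_kernel=config.conv_kernel,
            exact_zoh=config.exact_zoh,
        )
        self.heads = PredictionHeads(2 * config.d_out_effective, rng, hidden=config.head_hidden)
        # affine label transform [hr_mean, hr_scale, rr_mean, rr_scale]: the
        # regression heads predict (y - mean)/scale; identity by default.
        # Stored as a buffer so checkpoints carry it.
        self.target_stats = Tensor(np.array([0.0, 1.0, 0.0, 1.0], dtype=np.float32))

    # -- forward ----------------------------------------------------------
    def branch_features(self, batch: dict) -> dict[str, Tensor]:
        t = {k: v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float32))
             for k, v in batch.items()}
        L = t["left_eye"].shape[1]
        return {
            "left_eye": self.embed_left_eye(t["left_eye"]),
            "right_eye": self.embed_right_eye(t["right_eye"]),
            "mouth": self.embed_mouth(t["mouth"]),
            "facial": self.embed_facial(t["landmarks"]),
            "stmap": self.embed_stmap(t["stmap"], L),
        }

    def forward(self, batch: dict, return_intermediates: bool = False):
        branches = self.branch_features(batch)
        F = concat_features(branches)
        h_bi = self.encoder(F)
        fused = mean_pool(h_bi)
        hr, rr, cog = self.heads(fused)
        if return_intermediates:
            return (hr, rr, cog), {"F": F, "H_bi": h_bi, "h_fused": fused,
                                   "branches": branches}
        return hr, rr, cog


def save_checkpoint(model: MultiTaskModel, path: str | Path):
    """Single-archive checkpoint: named parameter/buffer arrays plus the
    full config embedded as JSON.  Save/load round-trips bit-exactly."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> MultiTaskModel:
    with np.load(path) as z:
        cfg_json = bytes(z["__config__"]).decode()
        config = ModelConfig(**json.loads(cfg_json))
        model = MultiTaskModel(config, seed=0)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model
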