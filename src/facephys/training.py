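"""Subject-wise splitting, the training loop, evaluation, and label rules."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .config import ModelConfig, TrainConfig
from .metrics import classification_metrics, regression_metrics
from .model import MultiTaskModel
from .objectives import lambda_schedule, smooth_l1, total_loss, truncated_ce

__all__ = [
    "subject_split",
    "nasa_tlx_label",
    "train",
    "evaluate",
    "depth_sweep",
    "TrainHistory",
]

_FEATURE_KEYS = ("left_eye", "right_eye", "mouth", "landmarks", "stmap")


def subject_split(subject_ids, seed: int, ratio=(0.6, 0.2, 0.2)) -> dict[str, str]:
    """Shuffle subjects by seed and partition them train/val/test.

    Sizes are round(r1*n) / round(r2*n) / remainder; every subject lands in
    exactly one split, so no subject's windows leak across splits.
    """
    subjects = sorted(set(map(str, subject_ids)))
    n = len(subjects)
    if n < 5:
        raise ValueError("need at least 5 subjects for a 6:2:2 split")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(n)]
    n_train = int(round(ratio[0] * n))
    n_val = int(round(ratio[1] * n))
    out = {}
    for i, s in enumerate(order):
        out[s] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
    return out


def nasa_tlx_label(score: float, scheme: str, ndrt_present: bool = False) -> str:
    """Threshold a NASA-TLX workload score into {low, high, excluded}.

    ``edream``: below 30 -> low, above 60 -> high, the 30-60 mid-band is
    excluded from classification.  ``mcdd``: normalized score > 10 together
    with a non-driving-related task -> high, otherwise low.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if scheme == "edream":
        if score < 30:
            return "low"
        if score > 60:
            return "high"
        return "excluded"
    if scheme == "mcdd":
        return "high" if (score > 10 and ndrt_present) else "low"
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class TrainHistory:
    steps: list = field(default_factory=list)  # per-step LossBundle
    val_steps: list = field(default_factory=list)  # (iter, val_L_total)
    best_iter: int = -1
    best_val: float = float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                iter=range(len(self.steps)),
                L_cog=[b.L_cog for b in self.steps],
                L_hr=[b.L_hr for b in self.steps],
                L_rr=[b.L_rr for b in self.steps],
                lam=[b.lam for b in self.steps],
                L_total=[b.L_total for b in self.steps],
            )
        )


def _subset(data: dict, mask: np.ndarray) -> dict:
    return {k: v[mask] for k, v in data.items()}


def split_dataset(data: dict, assignment: dict[str, str]) -> dict[str, dict]:
    splits = {}
    labels = np.array([assignment[s] for s in data["subject_id"]])
    for name in ("train", "val", "test"):
        splits[name] = _subset(data, labels == name)
    return splits


def _batch_tensors(data: dict, idx: np.ndarray) -> dict:
    return {k: Tensor(data[k][idx]) for k in _FEATURE_KEYS}


def _losses_on(model, data, idx, epsilon):
    batch = _batch_tensors(data, idx)
    hr, rr, cog = model(batch)
    hm, hs, rm, rs = model.target_stats.data
    L_cog = truncated_ce(cog, data["cog"][idx], epsilon=epsilon)
    L_hr = smooth_l1(hr, (data["hr"][idx] - hm) / hs)
    L_rr = smooth_l1(rr, (data["rr"][idx] - rm) / rs)
    return L_cog, L_hr, L_rr


def train(
    model: MultiTaskModel,
    train_data: dict,
    config: TrainConfig,
    val_data: dict | None = None,
) -> tuple[dict, TrainHistory]:
    """Minibatch training with the sigmoid-ramp multi-task weighting.

    Iterates ``iter_total`` steps of Adam, evaluating the joint objective on
    the validation set every ``val_every`` steps and keeping the best
    checkpoint (by validation L_total).  Fully reproducible given the seed.
    Returns (best_state_dict, history).
    """
    n = len(train_data["hr"])
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if config.normalize_targets:
        stats = []
        for key in ("hr", "rr"):
            stats += [float(train_data[key].mean()),
                      float(max(train_data[key].std(), 1e-6))]
        model.target_stats.data = np.array(stats, dtype=np.float32)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = copy.deepcopy(model.state_dict())
    order = rng.permutation(n)
    cursor = 0
    bs = min(config.batch_size, n)
    model.train()
    for it in range(config.iter_total):
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + bs]
        cursor += bs
        opt.zero_grad()
        L_cog, L_hr, L_rr = _losses_on(model, train_data, idx, config.epsilon)
        t, lam = lambda_schedule(it, config.iter_total, config.lambda_start_zero)
        total, bundle = total_loss(L_cog, L_hr, L_rr, lam, t)
        if not np.isfinite(bundle.L_total):
            raise FloatingPointError(
                f"non-finite loss at iter {it}: {bundle}"
            )
        total.backward()
        opt.step()
        history.steps.append(bundle)
        last = it == config.iter_total - 1
        if val_data is not None and len(val_data["hr"]) and (
            it % config.val_every == 0 or last
        ):
            val_total = _validation_loss(model, val_data, config, lam)
            history.val_steps.append((it, val_total))
            if val_total < history.best_val:
                history.best_val = val_total
                history.best_iter = it
                best_state = copy.deepcopy(model.state_dict())
    if val_data is None or not len(val_data["hr"]):
        best_state = copy.deepcopy(model.state_dict())
        history.best_iter = config.iter_total - 1
    model.load_state_dict(best_state)
    return best_state, history


def _validation_loss(model, data, config: TrainConfig, lam: float) -> float:
    model.eval()
    n = len(data["hr"])
    tot = 0.0
    with nn.no_grad():
        for lo in range(0, n, 32):
            idx = np.arange(lo, min(lo + 32, n))
            L_cog, L_hr, L_rr = _losses_on(model, data, idx, config.epsilon)
            _, bundle = total_loss(L_cog, L_hr, L_rr, lam)
            tot += bundle.L_total * len(idx)
    model.train()
    return tot / n


def predict(model: MultiTaskModel, data: dict, batch: int = 32):
    model.eval()
    n = len(data["hr"])
    hrs, rrs, cogs = [], [], []
    with nn.no_grad():
        for lo in range(0, n, batch):
            idx = np.arange(lo, min(lo + batch, n))
            hr, rr, cog = model(_batch_tensors(data, idx))
            hrs.append(hr.data)
            rrs.append(rr.data)
            cogs.append(cog.data)
    hm, hs, rm, rs = model.target_stats.data
    return (np.concatenate(hrs) * hs + hm,
            np.concatenate(rrs) * rs + rm,
            np.concatenate(cogs))


def evaluate(model: MultiTaskModel, data: dict, threshold: float = 0.5) -> dict:
    """Evaluation report over one split."""
    hr, rr, cog = predict(model, data)
    cm = classification_metrics(cog, data["cog"], threshold=threshold)
    hm = regression_metrics(hr, data["hr"])
    rm = regression_metrics(rr, data["rr"])
    return {
        "cog": {"acc": cm.accuracy, "f1": cm.f1, "sens": cm.sensitivity,
                "spec": cm.specificity},
        "hr": {"mae": hm.mae, "rmse": hm.rmse, "r": hm.pearson_r},
        "rr": {"mae": rm.mae, "rmse": rm.rmse, "r": rm.pearson_r},
        "n_windows": int(len(data["hr"])),
        "n_subjects": int(len(set(data["subject_id"].tolist()))),
    }


def depth_sweep(
    model_config: ModelConfig,
    train_config: TrainConfig,
    splits: dict[str, dict],
    depths: list[int],
) -> pd.DataFrame:
    """Train one model per encoder depth on identical data/seed and report
    test metrics per depth (controlled comparison)."""
    rows = []
    for depth in depths:
        cfg = copy.deepcopy(model_config)
        cfg.depth = depth
        model = MultiTaskModel(cfg, seed=train_config.seed)
        train(model, splits["train"], train_config, val_data=splits["val"])
        rep = evaluate(model, splits["test"], threshold=train_config.threshold)
        rows.append(
            dict(
                depth=depth,
                cog_acc=rep["cog"]["acc"],
                hr_mae=rep["hr"]["mae"],
                rr_mae=rep["rr"]["mae"],
                hr_r=rep["hr"]["r"],
                rr_r=rep["rr"]["r"],
            )
        )
    return pd.DataFrame(rows)
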