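"""Reference benchmark configurations and runners.

The *desk benchmark* is the package's standard CPU-scale experiment: 200
tensor-level synthetic windows from 10 subjects (the generator's default
cohort), 5-second windows at 30 fps, a narrow model (per-branch width 16,
three encoder layers per direction) trained for 400 Adam steps at batch 8.
It exists so that multi-task recovery and architecture trends can be
demonstrated end to end in minutes on one core; the full-scale defaults in
:mod:`facephys.config` are the GPU-scale recipe instead.

All sizes here are fixed: they define the experiment, and the test suite
and the acceptance script both run exactly this configuration.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig, TrainConfig
from .model import MultiTaskModel
from .synthetic import SyntheticConfig, dataset_to_arrays, generate_dataset
from .training import depth_sweep, evaluate, split_dataset, subject_split, train

__all__ = [
    "desk_synthetic_config",
    "desk_model_config",
    "desk_train_config",
    "make_desk_splits",
    "trivial_baselines",
    "run_desk_benchmark",
    "run_depth_sweep",
]

DESK_L = 150
DESK_FPS = 30.0
DESK_NOISE_SIGMA = 0.5  # high-SNR regime
DESK_ITERS = 400
DESK_BATCH = 8
DESK_LR = 2e-3


def desk_synthetic_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=10,
        windows_per_subject=20,
        fps=DESK_FPS,
        L=DESK_L,
        noise_sigma=DESK_NOISE_SIGMA,
        seed=seed,
    )


def desk_model_config(depth: int = 3) -> ModelConfig:
    return ModelConfig(
        d=16,
        depth=depth,
        subregion_c1=8,
        subregion_c2=16,
        landmark_channels=8,
        stmap_c1=8,
        state_dim=8,
        head_hidden=64,
        window_length=DESK_L,
    )


def desk_train_config(seed: int) -> TrainConfig:
    return TrainConfig(
        learning_rate=DESK_LR,
        batch_size=DESK_BATCH,
        iter_total=DESK_ITERS,
        seed=seed,
        val_every=50,
    )


def make_desk_splits(seed: int) -> tuple[dict, dict]:
    """Generate the desk dataset and split it subject-wise 6:2:2."""
    samples, manifest = generate_dataset(desk_synthetic_config(seed))
    data = dataset_to_arrays(samples)
    assignment = subject_split(data["subject_id"], seed=seed)
    return split_dataset(data, assignment), {"manifest": manifest, "assignment": assignment}


def trivial_baselines(train_data: dict, test_data: dict) -> dict:
    """Majority-class accuracy and global-mean-predictor MAEs."""
    counts = {c: int((train_data["cog"] == c).sum()) for c in (0, 1)}
    majority = max(counts, key=counts.get)
    return {
        "cog_acc": float((test_data["cog"] == majority).mean()),
        "hr_mae": float(np.abs(test_data["hr"] - train_data["hr"].mean()).mean()),
        "rr_mae": float(np.abs(test_data["rr"] - train_data["rr"].mean()).mean()),
    }


def run_desk_benchmark(seed: int, depth: int = 3) -> dict:
    """Train the desk model and report test metrics plus trivial baselines."""
    splits, _ = make_desk_splits(seed)
    model = MultiTaskModel(desk_model_config(depth), seed=seed)
    _, history = train(model, splits["train"], desk_train_config(seed),
                       val_data=splits["val"])
    report = evaluate(model, splits["test"])
    report["baselines"] = trivial_baselines(splits["train"], splits["test"])
    report["history"] = history
    report["depth"] = depth
    return report


def run_depth_sweep(seed: int, depths=(1, 3)) -> "pd.DataFrame":
    splits, _ = make_desk_splits(seed)
    return depth_sweep(desk_model_config(), desk_train_config(seed), splits, list(depths))
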