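"""A miniature end-to-end training run (a couple of minutes on one core).

Trains a narrow model on a small synthetic cohort with subject-wise
6:2:2 splitting and prints the loss trajectory and held-out metrics.
The full desk benchmark lives in facephys.benchmarks.
"""

from facephys.config import ModelConfig, TrainConfig
from facephys.model import MultiTaskModel
from facephys.synthetic import SyntheticConfig, dataset_to_arrays, generate_dataset
from facephys.training import evaluate, split_dataset, subject_split, train

data = dataset_to_arrays(
    generate_dataset(SyntheticConfig(n_subjects=6, windows_per_subject=6,
                                     L=60, noise_sigma=0.5, seed=0))[0]
)
splits = split_dataset(data, subject_split(data["subject_id"], seed=0))

model_cfg = ModelConfig(d=8, depth=1, subregion_c1=4, subregion_c2=8,
                        landmark_channels=4, stmap_c1=4, state_dim=4,
                        head_hidden=16, window_length=60)
train_cfg = TrainConfig(learning_rate=2e-3, batch_size=6, iter_total=80,
                        seed=0, val_every=20)

model = MultiTaskModel(model_cfg, seed=0)
_, history = train(model, splits["train"], train_cfg, val_data=splits["val"])

frame = history.to_frame()
print(frame.iloc[::20][["L_cog", "L_hr", "L_rr", "lam", "L_total"]].round(3).to_string())
print(f"\nbest validation loss {history.best_val:.3f} at iter {history.best_iter}")

report = evaluate(model, splits["test"])
print("\nheld-out subjects:")
print(f"  cognitive accuracy {report['cog']['acc']:.2f}")
print(f"  HR MAE {report['hr']['mae']:.2f} bpm, RR MAE {report['rr']['mae']:.2f} rpm")
print("(a run this small mainly demonstrates the pipeline; the desk "
      "benchmark uses 200 windows and 400 steps)")
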