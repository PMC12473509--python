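"""Window-archive serialization.

Two archive kinds, both plain ``.npz``:

* *pixel windows* — stacked frames/landmarks/labels/start_frame, the output
  of preprocessing and of the pixel-level generator;
* *tensor datasets* — the five aligned model-input arrays plus labels, the
  interchange format between the synthetic generator and training.

The synthetic path emits the same formats as the real-data path, so the two
are interchangeable downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocessing import Labels, VideoWindow

__all__ = ["save_windows", "load_windows", "save_dataset", "load_dataset"]

_NOLABEL = np.nan


def save_windows(windows: list[VideoWindow], path: str | Path):
    if not windows:
        raise ValueError("no windows to save")
    labels = np.array(
        [
            (w.labels.hr_bpm, w.labels.rr_rpm, w.labels.cog)
            if w.labels is not None
            else (_NOLABEL, _NOLABEL, _NOLABEL)
            for w in windows
        ]
    )
    np.savez_compressed(
        path,
        frames=np.stack([w.frames for w in windows]),
        landmarks=np.stack([w.landmarks for w in windows]),
        labels=labels,
        start_frame=np.array([w.start_frame for w in windows]),
        fps=np.array([w.fps for w in windows]),
        subject_id=np.array([w.subject_id for w in windows]),
        trial_id=np.array([w.trial_id for w in windows]),
    )


def load_windows(path: str | Path) -> list[VideoWindow]:
    with np.load(path, allow_pickle=False) as z:
        out = []
        for i in range(len(z["frames"])):
            lab = z["labels"][i]
            labels = (
                None
                if np.isnan(lab[0])
                else Labels(hr_bpm=float(lab[0]), rr_rpm=float(lab[1]), cog=int(lab[2]))
            )
            out.append(
                VideoWindow(
                    frames=z["frames"][i],
                    landmarks=z["landmarks"][i],
                    start_frame=int(z["start_frame"][i]),
                    fps=float(z["fps"][i]),
                    subject_id=str(z["subject_id"][i]),
                    trial_id=str(z["trial_id"][i]),
                    labels=labels,
                )
            )
    return out


def save_dataset(data: dict, path: str | Path):
    np.savez_compressed(path, **data)


def load_dataset(path: str | Path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        return {k: z[k] for k in z.files}
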