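"""Window segmentation and facial-region extraction.

Raw input is a stream of RGB frames with per-frame 106-point landmarks.  The
stream is cut into fixed-length windows (default L=300 frames) on a stride
(default s=30), and each window yields three fixed-size subregion clips
(left eye and right eye 25x25, mouth 15x35) plus the landmark sequence
normalized to [0,1] by the frame dimensions.

Which of the 106 points define each region is configuration: crops are
centered on the per-frame centroid of the region's landmark indices, with
the crop box clamped inside the frame so the output shape never changes.
The defaults below follow the common 106-point layout (eye contours at
indices 66-74 / 75-83, outer+inner lip at 84-103).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "REGION_SHAPES",
    "DEFAULT_REGION_LANDMARKS",
    "Labels",
    "FrameStream",
    "VideoWindow",
    "SubregionClip",
    "LandmarkWindow",
    "segment_windows",
    "crop_subregion",
    "normalize_landmarks",
    "denormalize_landmarks",
    "load_frame_stream",
]

#: fixed (height, width) of each subregion crop
REGION_SHAPES = {"left_eye": (25, 25), "right_eye": (25, 25), "mouth": (15, 35)}

#: default landmark-index sets for a 106-point scheme; override per detector
DEFAULT_REGION_LANDMARKS = {
    "left_eye": tuple(range(66, 75)),
    "right_eye": tuple(range(75, 84)),
    "mouth": tuple(range(84, 104)),
}

N_LANDMARKS = 106


@dataclass
class Labels:
    hr_bpm: float
    rr_rpm: float
    cog: int  # binary cognitive-load class


@dataclass
class FrameStream:
    """An ordered frame sequence with aligned landmarks."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    landmarks: np.ndarray  # (T, 106, 2) float, pixel coordinates
    fps: float
    subject_id: str = "unknown"
    trial_id: str = "unknown"
    labels: Labels | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if len(self.frames) != len(self.landmarks):
            raise ValueError(
                f"frames ({len(self.frames)}) and landmarks ({len(self.landmarks)}) "
                "must have equal length"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class VideoWindow:
    """An L-frame clip cut from a stream."""

    frames: np.ndarray  # (L, H, W, 3) uint8
    landmarks: np.ndarray  # (L, 106, 2) float
    start_frame: int
    fps: float
    subject_id: str = "unknown"
    trial_id: str = "unknown"
    labels: Labels | None = None
    stride: int | None = None  # segmentation stride, carried as metadata
    region_landmarks: dict = field(default_factory=lambda: dict(DEFAULT_REGION_LANDMARKS))

    @property
    def length(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class SubregionClip:
    region: str
    pixels: np.ndarray  # (L, 3, h, w) in [0, 1]


@dataclass
class LandmarkWindow:
    coords: np.ndarray  # (L, 106, 2) in [0, 1]


def segment_windows(
    stream: FrameStream, window_length: int = 300, stride: int = 30
) -> list[VideoWindow]:
    """Cut a stream into half-open windows [k*s, k*s + L).

    Returns floor((T - L)/s) + 1 windows for T >= L, otherwise none; windows
    shorter than L are never emitted.  Each window inherits the stream's
    labels and identifiers.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    T = len(stream.frames)
    windows = []
    for start in range(0, T - window_length + 1, stride):
        windows.append(
            VideoWindow(
                frames=stream.frames[start : start + window_length],
                landmarks=stream.landmarks[start : start + window_length],
                start_frame=start,
                fps=stream.fps,
                subject_id=stream.subject_id,
                trial_id=stream.trial_id,
                labels=stream.labels,
                stride=stride,
            )
        )
    return windows


def crop_subregion(window: VideoWindow, region: str) -> SubregionClip:
    """Extract the fixed-size crop for one facial region.

    The box is centered per frame on the centroid of the region's landmark
    indices and clamped fully inside the frame, so the output shape depends
    only on the region tag.  Pixels are rescaled to [0, 1].
    """
    if region not in REGION_SHAPES:
        raise KeyError(f"unknown region {region!r}; expected one of {list(REGION_SHAPES)}")
    h, w = REGION_SHAPES[region]
    H, W = window.frame_shape
    if H < h or W < w:
        raise ValueError(f"frame {H}x{W} smaller than {region} crop {h}x{w}")
    idx = list(window.region_landmarks[region])
    centers = window.landmarks[:, idx, :].mean(axis=1)  # (L, 2) as (x, y)
    out = np.empty((window.length, 3, h, w), dtype=np.float32)
    for t in range(window.length):
        cx, cy = centers[t]
        top = int(round(cy - h / 2))
        left = int(round(cx - w / 2))
        top = min(max(top, 0), H - h)
        left = min(max(left, 0), W - w)
        patch = window.frames[t, top : top + h, left : left + w, :]
        out[t] = patch.transpose(2, 0, 1).astype(np.float32) / 255.0
    return SubregionClip(region=region, pixels=out)


def normalize_landmarks(window: VideoWindow) -> LandmarkWindow:
    """Divide x by frame width and y by frame height, clamped to [0, 1]."""
    if not np.all(np.isfinite(window.landmarks)):
        raise ValueError("landmarks contain non-finite coordinates")
    H, W = window.frame_shape
    coords = window.landmarks.astype(np.float64).copy()
    coords[..., 0] /= W
    coords[..., 1] /= H
    return LandmarkWindow(coords=np.clip(coords, 0.0, 1.0))


def denormalize_landmarks(lm: LandmarkWindow, frame_shape: tuple[int, int]) -> np.ndarray:
    H, W = frame_shape
    out = lm.coords.copy()
    out[..., 0] *= W
    out[..., 1] *= H
    return out


def load_frame_stream(directory: str | Path) -> FrameStream:
    """Load a stream from a directory of numbered PNG/JPEG frames.

    Expects ``meta.json`` (fps, subject_id, trial_id, optional labels) and
    landmarks either as ``landmarks.csv`` with columns
    (frame, point_index, x, y) or ``landmarks.json`` holding a (T, 106, 2)
    array.
    """
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    frame_paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not frame_paths:
        raise FileNotFoundError(f"no PNG/JPEG frames in {directory}")
    frames = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in frame_paths])
    csv_path = directory / "landmarks.csv"
    if csv_path.exists():
        df = pd.read_csv(csv_path)
        T = len(frames)
        lm = np.full((T, N_LANDMARKS, 2), np.nan)
        lm[df["frame"].to_numpy(), df["point_index"].to_numpy(), 0] = df["x"].to_numpy()
        lm[df["frame"].to_numpy(), df["point_index"].to_numpy(), 1] = df["y"].to_numpy()
    else:
        lm = np.asarray(json.loads((directory / "landmarks.json").read_text()), dtype=float)
    labels = None
    if "labels" in meta:
        labels = Labels(**meta["labels"])
    return FrameStream(
        frames=frames,
        landmarks=lm,
        fps=float(meta["fps"]),
        subject_id=str(meta.get("subject_id", "unknown")),
        trial_id=str(meta.get("trial_id", "unknown")),
        labels=labels,
    )
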