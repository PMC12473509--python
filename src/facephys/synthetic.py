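"""Synthetic physiological-video generator.

Emulates the statistical structure of driving-study corpora at two fidelity
levels, so every stage of the pipeline is testable without the
access-restricted datasets:

* **pixel level** — a toy face (flat skin-tone ellipse on a canvas) whose
  green channel pulses at the heart-rate frequency with respiratory
  amplitude modulation, plus a direct low-frequency respiratory baseline,
  blink events (eye patches darkened for 150 ms) from a Poisson process
  whose rate depends on cognitive state, landmark jitter from a random-walk
  head motion, slow lighting drift, and additive Gaussian sensor noise.
  This exercises preprocessing and STMap construction end to end.
* **tensor level** — the five aligned model inputs built directly, with the
  same pulse/respiration signals embedded in the STMap rows and blink
  impulses in the eye-clip intensities.  This is what the training
  benchmarks consume; it skips video synthesis cost.

Per-subject baselines follow truncated normals (HR ~ N(70, 7) on [50, 95]
bpm, RR ~ N(15, 2) on [10, 22] rpm); high cognitive load shifts HR by
+8 bpm and RR by +2 rpm (plus unit-variance per-window jitter) and doubles
the blink rate (12 -> 24 blinks/min).  Labels equal the generating values
exactly.  Everything is deterministic given (seed, subject_index,
window_index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import (
    DEFAULT_REGION_LANDMARKS,
    REGION_SHAPES,
    Labels,
    VideoWindow,
)

__all__ = [
    "SubjectProfile",
    "SyntheticConfig",
    "WindowSample",
    "generate_subject",
    "generate_window",
    "generate_dataset",
    "dataset_to_arrays",
]

_SKIN_PALETTE = (
    (224, 172, 138),
    (198, 140, 110),
    (164, 110, 84),
    (120, 80, 60),
    (92, 62, 46),
)


@dataclass
class SubjectProfile:
    subject_id: str
    subject_index: int
    baseline_hr: float  # bpm, in [50, 95]
    baseline_rr: float  # rpm, in [10, 22]
    skin_tone: tuple[int, int, int]
    blink_rate_low: float  # blinks/min under low load
    blink_rate_high: float
    motion_amplitude: float  # px random-walk step scale
    pulse_gain: float  # per-subject rPPG amplitude scalar


@dataclass
class SyntheticConfig:
    n_subjects: int = 10
    windows_per_subject: int = 20
    fps: float = 30.0
    L: int = 300
    delta_hr_load: float = 8.0  # bpm added under high load
    delta_rr_load: float = 2.0  # rpm added under high load
    blink_rate_low: float = 12.0
    blink_rate_high: float = 24.0
    blink_duration_s: float = 0.150
    pulse_amplitude: float = 4.0  # 8-bit intensity units
    resp_mod_depth: float = 0.5
    noise_sigma: float = 1.0  # additive Gaussian, 8-bit units
    lighting_drift: float = 2.0  # amplitude of slow illumination sinusoid
    motion_amplitude: float = 1.0
    canvas: int = 128
    grid_rows: int = 5
    grid_cols: int = 5
    level: str = "tensor"  # "tensor" or "pixel"
    seed: int = 0


@dataclass
class WindowSample:
    """One generated window: labels plus either pixel- or tensor-level data."""

    subject_id: str
    window_index: int
    labels: Labels
    n_blinks: int
    window: VideoWindow | None = None  # pixel level
    tensors: dict | None = None  # tensor level: five aligned arrays


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def generate_subject(config: SyntheticConfig, subject_index: int) -> SubjectProfile:
    if subject_index >= config.n_subjects:
        raise IndexError("subject_index beyond n_subjects")
    rng = np.random.default_rng([config.seed, 1000 + subject_index])
    return SubjectProfile(
        subject_id=f"S{subject_index:03d}",
        subject_index=subject_index,
        baseline_hr=_truncated_normal(rng, 70.0, 7.0, 50.0, 95.0),
        baseline_rr=_truncated_normal(rng, 15.0, 2.0, 10.0, 22.0),
        skin_tone=_SKIN_PALETTE[int(rng.integers(len(_SKIN_PALETTE)))],
        blink_rate_low=config.blink_rate_low,
        blink_rate_high=config.blink_rate_high,
        motion_amplitude=config.motion_amplitude,
        pulse_gain=float(rng.uniform(0.8, 1.2)),
    )


def _landmark_template(canvas: int) -> np.ndarray:
    """Deterministic 106-point layout consistent with the default region
    index sets: face oval (0-65), left eye (66-74), right eye (75-83),
    mouth (84-103), nose (104-105)."""
    c = canvas / 2.0
    pts = np.zeros((106, 2))
    ang = np.linspace(0, 2 * np.pi, 66, endpoint=False)
    pts[0:66, 0] = c + 0.40 * canvas * np.cos(ang)
    pts[0:66, 1] = c + 0.46 * canvas * np.sin(ang)
    for start, (ex, ey) in ((66, (c - 0.18 * canvas, c - 0.12 * canvas)),
                            (75, (c + 0.18 * canvas, c - 0.12 * canvas))):
        a = np.linspace(0, 2 * np.pi, 9, endpoint=False)
        pts[start : start + 9, 0] = ex + 0.05 * canvas * np.cos(a)
        pts[start : start + 9, 1] = ey + 0.03 * canvas * np.sin(a)
    a = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts[84:104, 0] = c + 0.10 * canvas * np.cos(a)
    pts[84:104, 1] = c + 0.24 * canvas + 0.04 * canvas * np.sin(a)
    pts[104] = (c, c + 0.04 * canvas)
    pts[105] = (c, c + 0.10 * canvas)
    return pts


def _physio_signals(hr, rr, L, fps, resp_mod_depth):
    t = np.arange(L) / fps
    resp = np.sin(2 * np.pi * rr / 60.0 * t)
    pulse = np.sin(2 * np.pi * hr / 60.0 * t) * (1.0 + resp_mod_depth * resp)
    return pulse, resp


def _blink_mask(rng, rate_per_min, L, fps, duration_s):
    """Poisson blink process -> (per-frame closed mask, event count)."""
    duration_frames = max(1, int(round(duration_s * fps)))
    n = rng.poisson(rate_per_min * (L / fps) / 60.0)
    mask = np.zeros(L, dtype=bool)
    starts = np.sort(rng.integers(0, L, size=n))
    for s in starts:
        mask[s : s + duration_frames] = True
    return mask, int(n)


def generate_window(
    profile: SubjectProfile,
    cog_state: int,
    config: SyntheticConfig,
    window_index: int,
) -> WindowSample:
    rng = np.random.default_rng(
        [config.seed, 2000 + profile.subject_index, window_index]
    )
    hr = profile.baseline_hr + cog_state * config.delta_hr_load + rng.normal(0, 1)
    rr = profile.baseline_rr + cog_state * config.delta_rr_load + rng.normal(0, 1)
    labels = Labels(hr_bpm=float(hr), rr_rpm=float(rr), cog=int(cog_state))
    blink_rate = profile.blink_rate_high if cog_state else profile.blink_rate_low
    blink_mask, n_blinks = _blink_mask(
        rng, blink_rate, config.L, config.fps, config.blink_duration_s
    )
    if config.level == "pixel":
        window = _render_pixel_window(profile, labels, blink_mask, config, rng)
        return WindowSample(profile.subject_id, window_index, labels, n_blinks,
                            window=window)
    tensors = _render_tensor_window(profile, labels, blink_mask, config, rng)
    return WindowSample(profile.subject_id, window_index, labels, n_blinks,
                        tensors=tensors)


def _render_pixel_window(profile, labels, blink_mask, config, rng) -> VideoWindow:
    L, n = config.L, config.canvas
    fps = config.fps
    pulse, resp = _physio_signals(
        labels.hr_bpm, labels.rr_rpm, L, fps, config.resp_mod_depth
    )
    amp = config.pulse_amplitude * profile.pulse_gain
    t = np.arange(L) / fps
    drift = config.lighting_drift * np.sin(2 * np.pi * 0.05 * t)

    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = n / 2.0
    face = (((xx - cx) / (0.42 * n)) ** 2 + ((yy - cy) / (0.48 * n)) ** 2) <= 1.0

    template = _landmark_template(n)
    walk = np.cumsum(rng.normal(0, profile.motion_amplitude * 0.2, size=(L, 2)), axis=0)
    walk = np.clip(walk, -3 * profile.motion_amplitude, 3 * profile.motion_amplitude)
    landmarks = template[None, :, :] + walk[:, None, :]
    landmarks = np.clip(landmarks, 0, n - 1)

    base = np.zeros((n, n, 3), dtype=np.float64) + 40.0
    base[face] = profile.skin_tone

    eye_centers = [
        template[list(DEFAULT_REGION_LANDMARKS[r])].mean(axis=0)
        for r in ("left_eye", "right_eye")
    ]
    frames = np.empty((L, n, n, 3), dtype=np.uint8)
    for k in range(L):
        img = base.copy()
        # pulsatile color change, strongest in green; RR also enters as a
        # direct baseline oscillation (two recoverable signatures)
        img[face, 1] += amp * pulse[k] + 0.5 * amp * resp[k]
        img[face, 0] += 0.3 * amp * pulse[k]
        img[face, 2] += 0.2 * amp * pulse[k]
        img += drift[k]
        dx, dy = walk[k]
        for ex, ey in eye_centers:
            x0, y0 = int(ex + dx) - 6, int(ey + dy) - 4
            patch = img[max(y0, 0) : y0 + 8, max(x0, 0) : x0 + 12]
            if blink_mask[k]:
                patch *= 0.35  # closed lid: darkened eye region
            else:
                patch *= 0.75  # open eye is darker than skin
        if config.noise_sigma > 0:
            img += rng.normal(0, config.noise_sigma, img.shape)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)
    return VideoWindow(
        frames=frames,
        landmarks=landmarks,
        start_frame=0,
        fps=fps,
        subject_id=profile.subject_id,
        labels=labels,
    )


def _render_tensor_window(profile, labels, blink_mask, config, rng) -> dict:
    """Build the five aligned model inputs directly (units match the
    pixel-level path after rescaling to [0, 1])."""
    L, fps = config.L, config.fps
    pulse, resp = _physio_signals(
        labels.hr_bpm, labels.rr_rpm, L, fps, config.resp_mod_depth
    )
    amp01 = config.pulse_amplitude * profile.pulse_gain / 255.0
    noise01 = config.noise_sigma / 255.0
    H = config.grid_rows * config.grid_cols

    # STMap rows: pulse + respiratory baseline with per-cell gain/phase
    cell_gain = rng.uniform(0.7, 1.3, size=H)
    cell_phase = rng.uniform(-0.3, 0.3, size=H)
    tgrid = np.arange(L) / fps
    rows = np.sin(
        2 * np.pi * labels.hr_bpm / 60.0 * tgrid[None, :] + cell_phase[:, None]
    ) * (1.0 + config.resp_mod_depth * resp[None, :])
    rows = cell_gain[:, None] * (rows + 0.5 * resp[None, :])
    chan_scale = np.array([0.3, 1.0, 0.2])
    stmap = 0.5 + 0.5 * amp01 * 60.0 * chan_scale[:, None, None] * rows[None, :, :]
    stmap += rng.normal(0, noise01, stmap.shape)
    lo = stmap.min(axis=2, keepdims=True)
    hi = stmap.max(axis=2, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    stmap = (stmap - lo) / span

    tone01 = np.asarray(profile.skin_tone, dtype=np.float64) / 255.0

    def _clip_for(region: str, blink_sensitive: bool) -> np.ndarray:
        h, w = REGION_SHAPES[region]
        clip = np.empty((L, 3, h, w), dtype=np.float32)
        level = tone01[None, :] + amp01 * pulse[:, None] * np.array([0.3, 1.0, 0.2])
        if blink_sensitive:
            openness = np.where(blink_mask, 0.35, 0.75)
            level = level * openness[:, None]
        clip[:] = level[:, :, None, None]
        clip += rng.normal(0, noise01, clip.shape).astype(np.float32)
        return np.clip(clip, 0.0, 1.0)

    landmarks = _landmark_template(config.canvas)
    walk = np.cumsum(rng.normal(0, profile.motion_amplitude * 0.2, size=(L, 2)), axis=0)
    lm = np.clip(landmarks[None] + walk[:, None, :], 0, config.canvas - 1)
    lm = lm / config.canvas  # normalized coordinates, as the model expects

    return {
        "left_eye": _clip_for("left_eye", True),
        "right_eye": _clip_for("right_eye", True),
        "mouth": _clip_for("mouth", False),
        "landmarks": lm.astype(np.float32),
        "stmap": stmap.astype(np.float32),
    }


def generate_dataset(config: SyntheticConfig) -> tuple[list[WindowSample], pd.DataFrame]:
    """All windows for all subjects, cognitive classes balanced within
    subject, plus a manifest recording every profile and true label."""
    samples: list[WindowSample] = []
    rows = []
    for si in range(config.n_subjects):
        profile = generate_subject(config, si)
        for wi in range(config.windows_per_subject):
            cog = wi % 2  # balanced within subject
            s = generate_window(profile, cog, config, wi)
            samples.append(s)
            rows.append(
                dict(
                    subject_id=profile.subject_id,
                    window_id=f"{profile.subject_id}_w{wi:03d}",
                    cog=s.labels.cog,
                    hr_bpm=s.labels.hr_bpm,
                    rr_rpm=s.labels.rr_rpm,
                    baseline_hr=profile.baseline_hr,
                    baseline_rr=profile.baseline_rr,
                    n_blinks=s.n_blinks,
                    seed=config.seed,
                )
            )
    return samples, pd.DataFrame(rows)


def dataset_to_arrays(samples: list[WindowSample]) -> dict:
    """Stack tensor-level samples into batched arrays for training."""
    if any(s.tensors is None for s in samples):
        raise ValueError("dataset_to_arrays requires tensor-level samples")
    keys = ("left_eye", "right_eye", "mouth", "landmarks", "stmap")
    out = {k: np.stack([s.tensors[k] for s in samples]).astype(np.float32) for k in keys}
    out["hr"] = np.array([s.labels.hr_bpm for s in samples], dtype=np.float64)
    out["rr"] = np.array([s.labels.rr_rpm for s in samples], dtype=np.float64)
    out["cog"] = np.array([s.labels.cog for s in samples], dtype=np.int64)
    out["subject_id"] = np.array([s.subject_id for s in samples])
    return out
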