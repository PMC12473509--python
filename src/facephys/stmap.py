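"""Spatio-temporal map (STMap) construction and an FFT rate oracle.

The STMap is the standard input representation for rPPG networks: the face
bounding box (here the axis-aligned box of all landmarks) is divided into a
grid of ROIs, the mean R, G, B of each cell is recorded per frame, and each
(channel, cell) time series is min-max normalized over the window.  The
result is a 3 x H x L image whose rows carry the pulsatile color signal.

``oracle_rate_from_stmap`` reads a periodic rate straight off the map with a
band-limited FFT.  It exists as an independent check (the learned model is
the estimator of record): the synthetic generator embeds a known pulse and
the oracle must recover it, which pins down the whole frames -> STMap ->
spectrum chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import VideoWindow

__all__ = ["STMap", "RateEstimate", "build_stmap", "oracle_rate_from_stmap"]


@dataclass
class STMap:
    values: np.ndarray  # (3, H, L) in [0, 1]; channel order R, G, B
    fps: float
    grid: tuple[int, int]  # (rows, cols); H = rows * cols, row-major


@dataclass
class RateEstimate:
    rate_per_min: float | None  # None when no oscillation is present
    confidence: float  # peak-to-median band power ratio; 0 for flat input


def build_stmap(window: VideoWindow, grid_rows: int = 5, grid_cols: int = 5) -> STMap:
    """Build the grid-ROI color map for one window.

    Rows are ordered row-major over (grid_row, grid_col); channels R, G, B.
    Degenerate (constant) series normalize to 0.5.
    """
    lm = window.landmarks
    x0, y0 = lm[..., 0].min(), lm[..., 1].min()
    x1, y1 = lm[..., 0].max(), lm[..., 1].max()
    H_img, W_img = window.frame_shape
    x0, x1 = max(int(np.floor(x0)), 0), min(int(np.ceil(x1)), W_img)
    y0, y1 = max(int(np.floor(y0)), 0), min(int(np.ceil(y1)), H_img)
    if x1 - x0 < grid_cols or y1 - y0 < grid_rows:
        raise ValueError("landmark bounding box too small for the ROI grid")

    L = window.length
    n_cells = grid_rows * grid_cols
    ys = np.linspace(y0, y1, grid_rows + 1).astype(int)
    xs = np.linspace(x0, x1, grid_cols + 1).astype(int)
    raw = np.empty((3, n_cells, L), dtype=np.float64)
    for r in range(grid_rows):
        for c in range(grid_cols):
            cell = window.frames[:, ys[r] : ys[r + 1], xs[c] : xs[c + 1], :]
            raw[:, r * grid_cols + c, :] = cell.mean(axis=(1, 2)).T

    lo = raw.min(axis=2, keepdims=True)
    hi = raw.max(axis=2, keepdims=True)
    span = hi - lo
    degenerate = span[..., 0] == 0
    span[span == 0] = 1.0
    values = (raw - lo) / span
    values[degenerate] = 0.5
    return STMap(values=values.astype(np.float32), fps=window.fps, grid=(grid_rows, grid_cols))


def oracle_rate_from_stmap(stmap: STMap, band: tuple[float, float]) -> RateEstimate:
    """Dominant in-band frequency of the green channel, in cycles/minute.

    Averages the power spectra of all green rows, restricts to ``band`` (Hz)
    and returns 60 * argmax frequency.  Confidence is the ratio of the peak
    power to the median in-band power; flat maps return confidence 0 and an
    undefined rate.
    """
    low, high = band
    if not (0 < low < high < stmap.fps / 2):
        raise ValueError("band must satisfy 0 < low < high < fps/2")
    green = stmap.values[1].astype(np.float64)  # (H, L)
    green = green - green.mean(axis=1, keepdims=True)
    if np.allclose(green, 0):
        return RateEstimate(rate_per_min=None, confidence=0.0)
    L = green.shape[1]
    freqs = np.fft.rfftfreq(L, d=1.0 / stmap.fps)
    power = (np.abs(np.fft.rfft(green, axis=1)) ** 2).mean(axis=0)
    in_band = (freqs >= low) & (freqs <= high)
    if not np.any(in_band):
        raise ValueError("band empty after frequency discretization")
    band_power = power[in_band]
    band_freqs = freqs[in_band]
    peak = band_power.max()
    med = np.median(band_power)
    confidence = float(peak / med) if med > 0 else float("inf")
    rate = float(60.0 * band_freqs[np.argmax(band_power)])
    return RateEstimate(rate_per_min=rate, confidence=confidence)
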