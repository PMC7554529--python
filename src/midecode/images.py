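"""Time-frequency input images for the CNN decoder.

Each 8-s trial yields 11 sliding 2-s analysis windows over the 3-7 s
imagery interval (200 ms hop; window end times 5.0, 5.2, ..., 7.0 s).
Per window and channel a magnitude STFT spectrogram is computed (64-sample
Hamming taper, 50-sample overlap, 512 FFT points -> 257 x 32), from which
the theta-alpha band (4-13 Hz, 20 rows) and the beta band (13-32 Hz,
41 rows, cubic-interpolated down to 20) are cut and stacked vertically
into a 40 x 32 plane; the three channels are stacked depthwise, giving a
40 x 32 x 3 image per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.signal import get_window

from .trials import CHANNELS, Trial

THETA_ALPHA_BAND_HZ = (4.0, 13.0)
BETA_BAND_HZ = (13.0, 32.0)
#: rows per band block in the final image
BAND_ROWS = 20
IMAGE_SHAPE = (40, 32, 3)


@dataclass(frozen=True)
class SegmentGrid:
    """Sliding-window grid over the imagery interval."""

    window_length: float = 2.0
    hop: float = 0.2
    interval: tuple[float, float] = (3.0, 7.0)

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if self.window_length <= 0 or self.hop <= 0 or hi - lo < self.window_length:
            raise ValueError(f"invalid segment grid {self}")

    @property
    def n_segments(self) -> int:
        lo, hi = self.interval
        return int(round((hi - lo - self.window_length) / self.hop)) + 1

    @property
    def window_end_times(self) -> np.ndarray:
        """Decoding instants: the end time of each window, in seconds."""
        lo, _ = self.interval
        return lo + self.window_length + self.hop * np.arange(self.n_segments)


@dataclass(frozen=True)
class StftParams:
    window_samples: int = 64
    overlap_samples: int = 50
    n_fft: int = 512
    window_function: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_samples < self.window_samples:
            raise ValueError("overlap must be < window length")
        if self.n_fft < self.window_samples:
            raise ValueError("n_fft must be >= window length")

    @property
    def hop_samples(self) -> int:
        return self.window_samples - self.overlap_samples

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.window_samples) // self.hop_samples + 1

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1


DEFAULT_GRID = SegmentGrid()
DEFAULT_STFT = StftParams()


def segment_trial(trial: Trial, grid: SegmentGrid = DEFAULT_GRID) -> np.ndarray:
    """Cut the sliding 2-s windows out of a trial.

    Returns an array of shape (n_segments, 3, window samples); segment k
    spans [interval_start + k*hop, +window_length) — half-open in samples.
    """
    fs = trial.sampling_rate
    lo, hi = grid.interval
    if trial.duration < hi - 1e-9:
        raise ValueError(
            f"trial of {trial.duration:.3f}s too short for interval ending {hi}s"
        )
    win = int(round(grid.window_length * fs))
    segs = np.empty((grid.n_segments, trial.data.shape[0], win))
    for k in range(grid.n_segments):
        start = int(round((lo + k * grid.hop) * fs))
        segs[k] = trial.data[:, start:start + win]
    return segs


def compute_spectrogram(x: np.ndarray,
                        params: StftParams = DEFAULT_STFT) -> np.ndarray:
    """Magnitude STFT of a single-channel segment.

    The signal is split into frames of ``window_samples`` advanced by
    ``window_samples - overlap_samples``, tapered, and zero-padded to
    ``n_fft`` points; output shape is (n_fft//2 + 1) x n_frames — 257 x 32
    for a 500-sample segment under the defaults.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size < params.window_samples:
        raise ValueError(
            f"segment of {x.size} samples shorter than the "
            f"{params.window_samples}-sample analysis window"
        )
    taper = get_window(params.window_function, params.window_samples, fftbins=False)
    frames = sliding_window_view(x, params.window_samples)[::params.hop_samples]
    spec = np.fft.rfft(frames * taper, n=params.n_fft, axis=1)
    return np.abs(spec).T


def band_bins(band_hz: tuple[float, float], sampling_rate: float,
              n_fft: int) -> tuple[int, int]:
    """Inclusive bin range for a frequency band.

    Rows for [f_lo, f_hi] are bins floor(f_lo*n_fft/fs) .. ceil(f_hi*n_fft/fs):
    20 bins for 4-13 Hz and 41 for 13-32 Hz at fs=250, n_fft=512.
    """
    lo, hi = band_hz
    first = int(np.floor(lo * n_fft / sampling_rate))
    last = int(np.ceil(hi * n_fft / sampling_rate))
    return first, last


def _band_slice(spec: np.ndarray, band_hz: tuple[float, float],
                sampling_rate: float, n_fft: int) -> np.ndarray:
    first, last = band_bins(band_hz, sampling_rate, n_fft)
    sl = spec[first:last + 1]
    if sl.shape[0] == 0:
        raise ValueError(f"band {band_hz} Hz selects no spectrogram rows")
    return sl


def _interp_rows(block: np.ndarray, n_rows: int) -> np.ndarray:
    """Cubic interpolation along the frequency axis onto ``n_rows`` evenly
    spaced points spanning the block, per time column."""
    src = np.arange(block.shape[0])
    tgt = np.linspace(0, block.shape[0] - 1, n_rows)
    return CubicSpline(src, block, axis=0)(tgt)


def build_input_image(segment: np.ndarray,
                      params: StftParams = DEFAULT_STFT,
                      sampling_rate: float = 250.0) -> np.ndarray:
    """Build the 40 x 32 x 3 image for one 3-channel window.

    Per channel: theta-alpha rows (20 x 32) stacked over the
    cubic-interpolated beta rows (41 x 32 -> 20 x 32); channels (C3, Cz,
    C4) stacked depthwise.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2 or segment.shape[0] != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} x samples, got {segment.shape}")
    planes = []
    for ch in segment:
        spec = compute_spectrogram(ch, params)
        theta_alpha = _band_slice(spec, THETA_ALPHA_BAND_HZ, sampling_rate,
                                  params.n_fft)
        beta = _band_slice(spec, BETA_BAND_HZ, sampling_rate, params.n_fft)
        # cubic overshoot may dip below zero; magnitudes stay non-negative
        beta_small = np.maximum(_interp_rows(beta, BAND_ROWS), 0.0)
        planes.append(np.vstack([theta_alpha, beta_small]))
    return np.stack(planes, axis=-1)


def normalize_image(image: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-image normalization ahead of the CNN.  ``minmax`` maps onto
    [0, 1]; a constant image maps to zeros.  ``none`` passes through."""
    if method == "none":
        return image
    if method != "minmax":
        raise ValueError(f"unknown normalization {method!r}")
    lo, hi = image.min(), image.max()
    if hi - lo == 0:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def trial_images(trial: Trial,
                 grid: SegmentGrid = DEFAULT_GRID,
                 params: StftParams = DEFAULT_STFT,
                 normalize: str = "minmax") -> np.ndarray:
    """All images of a trial: shape (n_segments, 40, 32, 3)."""
    segs = segment_trial(trial, grid)
    imgs = np.stack([
        normalize_image(
            build_input_image(seg, params, sampling_rate=trial.sampling_rate),
            normalize,
        )
        for seg in segs
    ])
    return imgs
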