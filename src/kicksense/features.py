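"""Spectral min/max feature extraction.

Each motion window is converted into a short-time Fourier transform (STFT)
power-density pool per sensor, from which the S smallest and L largest
densities are kept.  The result is an ordered 4-column matrix per window —
(SA_i, LA_i, SG_i, LG_i): ascending accelerometer minima, descending
accelerometer maxima, and likewise for the gyroscope — a compact spectral
signature chosen for low latency relative to convolutional feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import get_window

from .core import MotionWindow
from .exceptions import ConfigurationError, EmptyInputError

WINDOW_FUNCTIONS = {"hamming": "hamming", "hann": "hann", "rectangular": "boxcar"}

PROVENANCE_ORIGINAL = "original"
PROVENANCE_LEVEL1 = "augmented-level1"
PROVENANCE_LEVEL2 = "augmented-level2"


@dataclass
class Spectrogram:
    """Complex STFT coefficients on a (frame, frequency-bin) grid."""

    frames: np.ndarray  # (n_frames, frame_len) complex
    window_fn: str
    frame_len: int
    hop: int
    sampling_rate: float = 50.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def stft(
    signal: np.ndarray,
    frame_len: int = 16,
    hop: int = 8,
    window_fn: str = "hamming",
) -> Spectrogram:
    """Short-time Fourier transform of a 1-D real signal.

    The signal is cut into frames of ``frame_len`` samples advancing by
    ``hop`` (50% overlap at the defaults), each frame is tapered by the
    chosen window function to limit spectral leakage, and the DFT of each
    tapered frame is taken.  Frame t, bin k holds
    ``sum_n signal[t*hop + n] * w[n] * exp(-2j*pi*k*n/frame_len)``.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if window_fn not in WINDOW_FUNCTIONS:
        raise ConfigurationError(
            f"window_fn must be one of {sorted(WINDOW_FUNCTIONS)}, got {window_fn!r}"
        )
    if hop < 1:
        raise ConfigurationError(f"hop must be >= 1, got {hop}")
    if signal.size < frame_len:
        raise EmptyInputError(
            f"signal of length {signal.size} shorter than frame_len {frame_len}"
        )
    w = get_window(WINDOW_FUNCTIONS[window_fn], frame_len, fftbins=True)
    n_frames = (signal.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = np.fft.fft(signal[idx] * w[None, :], axis=1)
    return Spectrogram(frames=frames, window_fn=window_fn, frame_len=frame_len, hop=hop)


def power_densities(spec: Spectrogram) -> np.ndarray:
    """Pool |coefficient|^2 over every time-frequency cell of the window."""
    if spec.n_frames == 0:
        raise EmptyInputError("empty spectrogram")
    return (np.abs(spec.frames) ** 2).ravel()


def select_minmax(
    densities: np.ndarray, S: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the S smallest densities (ascending) and L largest (descending).

    Duplicates are kept — multiset semantics: all-equal input yields S (or L)
    copies of the shared value.
    """
    d = np.asarray(densities, dtype=float).ravel()
    if S < 1 or L < 1:
        raise ConfigurationError(f"S and L must be >= 1, got S={S}, L={L}")
    if d.size < max(S, L):
        raise ConfigurationError(
            f"need at least max(S, L)={max(S, L)} densities, have {d.size}"
        )
    s = np.sort(d)
    return s[:S].copy(), s[::-1][:L].copy()


@dataclass
class FeatureConfig:
    """Knobs of the spectral feature stage.

    frame_len/hop default to 16/8 samples (50% frame overlap); window_fn
    defaults to Hamming.  S and L are the number of minimum and maximum
    power densities retained per sensor and must be equal.  channel_mode
    'norm' pools densities of the Euclidean norm of the three axes per
    sensor (robust to sensor-placement displacement); 'per-axis' keeps one
    density pool per axis (2 columns per channel).
    """

    frame_len: int = 16
    hop: int = 8
    window_fn: str = "hamming"
    S: int = 50
    L: int = 50
    channel_mode: str = "norm"

    def __post_init__(self) -> None:
        if self.S != self.L:
            raise ConfigurationError(f"S and L must be equal, got S={self.S}, L={self.L}")
        if self.channel_mode not in ("norm", "per-axis"):
            raise ConfigurationError(f"unknown channel_mode {self.channel_mode!r}")


@dataclass(eq=False)
class SpectralFeatureMatrix:
    """Ordered min/max spectral features of one motion window.

    In the default norm mode ``values`` has 4 columns — (SA, LA, SG, LG):
    ascending accelerometer minima, descending accelerometer maxima, then
    the gyroscope pair — and S rows.  The feature-vector count of the
    window is S + L (min set plus max set, both sensors combined).
    """

    values: np.ndarray  # (S, 2 * n_pools)
    S: int
    L: int
    class_label: Optional[str] = None
    intensity_label: Optional[float] = None
    subject_id: Optional[str] = None
    provenance: str = PROVENANCE_ORIGINAL
    columns: tuple = ("SA", "LA", "SG", "LG")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_feature_vectors(self) -> int:
        """S minimum plus L maximum power densities per window."""
        return self.S + self.L

    def validate(self) -> None:
        """Check ordering and nonnegativity invariants (original provenance)."""
        v = self.values
        if np.any(v < 0):
            raise ConfigurationError("power densities must be nonnegative")
        for j in range(0, v.shape[1], 2):
            s_col, l_col = v[:, j], v[:, j + 1]
            if np.any(np.diff(s_col) < 0):
                raise ConfigurationError(f"minima column {j} not non-decreasing")
            if np.any(np.diff(l_col) > 0):
                raise ConfigurationError(f"maxima column {j + 1} not non-increasing")
            if self.provenance == PROVENANCE_ORIGINAL and np.max(s_col) > np.min(l_col):
                raise ConfigurationError("a minimum exceeds a maximum from the same pool")

    def with_values(self, values: np.ndarray, provenance: str) -> "SpectralFeatureMatrix":
        """Copy labels/columns onto a new value matrix (augmentation helper)."""
        return replace(self, values=values, provenance=provenance)


def _density_pools(win: MotionWindow, cfg: FeatureConfig) -> list[np.ndarray]:
    """One pooled density multiset per sensor (norm mode) or per axis."""
    x = win.values
    n_ch = x.shape[1]
    if cfg.channel_mode == "norm":
        if n_ch % 3 != 0:
            raise ConfigurationError(
                f"norm mode needs channel count divisible by 3, got {n_ch}"
            )
        pools = [
            np.linalg.norm(x[:, 3 * s : 3 * s + 3], axis=1) for s in range(n_ch // 3)
        ]
    else:
        pools = [x[:, j] for j in range(n_ch)]
    return [
        power_densities(stft(sig, cfg.frame_len, cfg.hop, cfg.window_fn))
        for sig in pools
    ]


_NORM_COLS = ("SA", "LA", "SG", "LG")


def extract_features(win: MotionWindow, cfg: FeatureConfig) -> SpectralFeatureMatrix:
    """Convert a motion window into its spectral min/max feature matrix.

    Accelerometer densities fill the (SA, LA) column pair and gyroscope
    densities the (SG, LG) pair; with S = L = 50 the window contributes
    100 feature vectors, with S = L = 100 it contributes 200.
    """
    pools = _density_pools(win, cfg)
    cols = []
    for pool in pools:
        mins, maxs = select_minmax(pool, cfg.S, cfg.L)
        cols.extend([mins, maxs])
    values = np.column_stack(cols)
    if cfg.channel_mode == "norm" and len(pools) == 2:
        columns = _NORM_COLS
    else:
        columns = tuple(
            f"{sl}{j}" for j in range(len(pools)) for sl in ("S", "L")
        )
    return SpectralFeatureMatrix(
        values=values,
        S=cfg.S,
        L=cfg.L,
        class_label=win.class_label,
        intensity_label=win.intensity_label,
        subject_id=win.subject_id,
        provenance=PROVENANCE_ORIGINAL,
        columns=columns,
    )
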