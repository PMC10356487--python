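"""Denoising and peak-based segmentation of raw IMU streams."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .core import IMURecording, MotionWindow
from .exceptions import ConfigurationError, EmptyInputError


def moving_average_3pt(signal: np.ndarray) -> np.ndarray:
    """Three-point moving-average filter, length preserving.

    out[i] = mean(signal[i-1 .. i+1]); at the boundaries the window shrinks
    to the two available samples, avoiding padding bias.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("moving_average_3pt on empty signal")
    if x.size == 1:
        return x.copy()
    if x.size == 2:  # both windows shrink to the same two samples
        return np.full(2, x.mean())
    sums = np.convolve(x, np.ones(3), mode="same")
    counts = np.full(x.size, 3.0)
    counts[0] = counts[-1] = 2.0
    return sums / counts


def _filtered_magnitude(rec: IMURecording) -> np.ndarray:
    """Euclidean norm of the 3-pt-filtered accelerometer channels."""
    filt = np.column_stack([moving_average_3pt(rec.accel[:, j]) for j in range(3)])
    return np.linalg.norm(filt, axis=1)


def segment_by_peaks(
    rec: IMURecording,
    window_len: int = 128,
    min_peak_height: float = 1.0,
    min_separation: Optional[int] = None,
) -> list[MotionWindow]:
    """Segment a recording into one window per detected motion burst.

    Peaks are detected on the Euclidean norm of the filtered acceleration.
    Candidate peaks above ``min_peak_height`` are kept greedily by
    descending height (earlier index wins ties) subject to
    ``min_separation`` samples between kept peaks; each kept peak is the
    center of a ``window_len``-sample window, and windows that would cross
    the recording boundary are discarded.  Inside each window, continuous
    feature extraction advances STFT frames by half a frame (50% overlap).
    """
    if window_len < 4:
        raise ConfigurationError(f"window_len must be >= 4, got {window_len}")
    if window_len > len(rec):
        raise EmptyInputError(
            f"window_len {window_len} exceeds recording length {len(rec)}"
        )
    if min_separation is None:
        min_separation = window_len // 2
    mag = _filtered_magnitude(rec)
    candidates, props = find_peaks(mag, height=min_peak_height)
    if candidates.size == 0:
        return []
    heights = props["peak_heights"]
    # greedy separation rule: tallest first, earlier index breaks ties
    order = sorted(range(candidates.size), key=lambda i: (-heights[i], candidates[i]))
    kept: list[int] = []
    for i in order:
        p = candidates[i]
        if all(abs(p - q) >= min_separation for q in kept):
            kept.append(p)
    windows = []
    half = window_len // 2
    for p in sorted(kept):
        start = p - half
        end = start + window_len
        if start < 0 or end > len(rec):
            continue
        windows.append(MotionWindow(recording=rec, start=start, end=end))
    return windows


def match_windows_to_truth(
    detected: list[MotionWindow],
    truth: list[MotionWindow],
    max_offset: Optional[int] = None,
) -> list[MotionWindow]:
    """Copy labels from ground-truth windows onto detected windows.

    Each detected window inherits the labels of the nearest ground-truth
    window (by center) within ``max_offset`` samples (default: half the
    window length); unmatched detections are dropped.
    """
    out = []
    if not truth:
        return out
    centers = np.array([t.center for t in truth])
    for w in detected:
        lim = max_offset if max_offset is not None else len(w) // 2
        j = int(np.argmin(np.abs(centers - w.center)))
        if abs(int(centers[j]) - w.center) <= lim:
            out.append(
                MotionWindow(
                    recording=w.recording,
                    start=w.start,
                    end=w.end,
                    class_label=truth[j].class_label,
                    intensity_label=truth[j].intensity_label,
                    subject_id=w.subject_id,
                )
            )
    return out
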