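"""Core in-memory containers: raw IMU recordings and motion windows.

A recording is the 6-axis stream of one subject (tri-axial accelerometer +
tri-axial gyroscope) with a declared sampling rate and mandatory unit
metadata.  A motion window is a fixed-length slice of a recording — or, for
pre-windowed public datasets, a standalone array — optionally carrying a
motion-class label and a nonnegative intensity label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import FormatError

#: canonical internal units
ACCEL_UNITS = "m/s^2"
GYRO_UNITS = "deg/s"

#: conversion factors applied at load time
_G_TO_MS2 = 9.80665
_RAD_TO_DEG = 180.0 / np.pi


@dataclass
class IMURecording:
    """Timestamped 6-axis inertial stream for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    timestamps : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Tri-axial acceleration in m/s^2 (internal canonical unit).
    gyro : ndarray, shape (n, 3)
        Tri-axial angular velocity in deg/s (internal canonical unit).
    metadata : dict
        Must declare ``accel_units`` and ``gyro_units``; may carry a
        device tag and arbitrary provenance.
    """

    subject_id: str
    sampling_rate: float
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise FormatError(
                f"channel lengths disagree: {n} timestamps, accel "
                f"{self.accel.shape}, gyro {self.gyro.shape}"
            )
        if not self.sampling_rate > 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if n > 1:
            dt = np.diff(self.timestamps)
            bad = np.flatnonzero(dt <= 0)
            if bad.size:
                raise FormatError(
                    f"timestamps not strictly increasing at row {bad[0] + 1}"
                )
        if "accel_units" not in self.metadata or "gyro_units" not in self.metadata:
            raise FormatError(
                "unit declarations are mandatory: metadata must contain "
                "'accel_units' and 'gyro_units'"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def signal(self) -> np.ndarray:
        """All six channels as an (n, 6) array: accel xyz then gyro xyz."""
        return np.hstack([self.accel, self.gyro])


def convert_units(
    accel: np.ndarray, gyro: np.ndarray, accel_units: str, gyro_units: str
) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw channel arrays to the canonical m/s^2 and deg/s."""
    if accel_units == "g":
        accel = accel * _G_TO_MS2
    elif accel_units != ACCEL_UNITS:
        raise FormatError(f"unknown accelerometer unit {accel_units!r}")
    if gyro_units == "rad/s":
        gyro = gyro * _RAD_TO_DEG
    elif gyro_units != GYRO_UNITS:
        raise FormatError(f"unknown gyroscope unit {gyro_units!r}")
    return accel, gyro


@dataclass
class MotionWindow:
    """A fixed-length segment of an IMU stream, optionally labeled.

    Windows use 0-based, half-open ``[start, end)`` sample indices into
    ``recording``.  Pre-windowed datasets (e.g. the UCI-HAR text layout)
    instead populate ``data`` directly with an (n_samples, n_channels)
    array and leave ``recording`` unset.
    """

    recording: Optional[IMURecording] = None
    start: int = 0
    end: int = 0
    class_label: Optional[str] = None
    intensity_label: Optional[float] = None
    subject_id: Optional[str] = None
    data: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data is not None:
            self.data = np.asarray(self.data, dtype=float)
            if self.end == 0:
                self.end = self.data.shape[0]
        else:
            if self.recording is None:
                raise FormatError("MotionWindow needs a recording or a data array")
            if not (0 <= self.start < self.end <= len(self.recording)):
                raise FormatError(
                    f"window [{self.start}, {self.end}) outside recording of "
                    f"length {len(self.recording)}"
                )
        if self.subject_id is None and self.recording is not None:
            self.subject_id = self.recording.subject_id

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def values(self) -> np.ndarray:
        """Window samples as an (n, n_channels) array (accel then gyro)."""
        if self.data is not None:
            return self.data
        return self.recording.signal[self.start : self.end]

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2
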