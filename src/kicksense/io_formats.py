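"""On-disk dialects: raw IMU CSV, the UCI-HAR text layout, feature datasets.

Raw recordings are delimited text with a timestamp column and six channel
columns; the column mapping and unit declarations come from an explicit
schema.  Feature datasets round-trip through a versioned CSV with a
'#'-prefixed metadata header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentedDataset
from .core import IMURecording, MotionWindow, convert_units
from .exceptions import EmptyInputError, FormatError, SchemaError
from .features import SpectralFeatureMatrix

#: default raw-CSV column mapping (what `kicksense simulate` writes)
DEFAULT_SCHEMA = {
    "timestamp": "t",
    "accel": ("ax", "ay", "az"),
    "gyro": ("gx", "gy", "gz"),
    "accel_units": "m/s^2",
    "gyro_units": "deg/s",
    "delimiter": ",",
}

UCIHAR_LABELS = {
    1: "WALKING",
    2: "WALKING_UPSTAIRS",
    3: "WALKING_DOWNSTAIRS",
    4: "SITTING",
    5: "STANDING",
    6: "LAYING",
}

_FEATURE_MAGIC = "# kicksense-features v1"


@dataclass
class LoadReport:
    """Bookkeeping of one raw-CSV load."""

    n_rows: int
    n_dropped: int


def read_imu_csv(
    path, schema: Optional[dict] = None, subject_id: Optional[str] = None
) -> tuple[IMURecording, LoadReport]:
    """Read a raw 6-axis IMU recording from delimited text.

    Rows with any non-finite value are dropped and counted in the returned
    :class:`LoadReport`.  The sampling rate is the schema's explicit
    ``sampling_rate`` if present, otherwise the median reciprocal timestamp
    difference.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    for key in ("timestamp", "accel", "gyro", "accel_units", "gyro_units"):
        if key not in schema or schema[key] is None:
            raise SchemaError(f"schema is missing required entry {key!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    df = pd.read_csv(path, sep=schema.get("delimiter", ","))
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")
    cols = [schema["timestamp"], *schema["accel"], *schema["gyro"]]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing columns {missing}")
    data = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = np.isfinite(data).all(axis=1)
    n_dropped = int((~finite).sum())
    data = data[finite]
    if data.shape[0] == 0:
        raise EmptyInputError(f"{path}: no finite rows remain after filtering")
    t = data[:, 0]
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise FormatError(f"{path}: timestamps not increasing at row {bad[0] + 1}")
    rate = schema.get("sampling_rate")
    if rate is None:
        rate = 1.0 / float(np.median(dt)) if len(t) > 1 else 1.0
    accel, gyro = convert_units(
        data[:, 1:4], data[:, 4:7], schema["accel_units"], schema["gyro_units"]
    )
    rec = IMURecording(
        subject_id=subject_id or path.stem,
        sampling_rate=float(rate),
        timestamps=t,
        accel=accel,
        gyro=gyro,
        metadata={
            "accel_units": "m/s^2",
            "gyro_units": "deg/s",
            "source": str(path),
        },
    )
    return rec, LoadReport(n_rows=len(rec), n_dropped=n_dropped)


def _ucihar_signal(dirpath: Path, name: str, split: str) -> np.ndarray:
    f = dirpath / f"{name}_{split}.txt"
    if not f.exists():
        raise FormatError(f"missing UCI-HAR signal file {f}")
    return np.loadtxt(f, ndmin=2)


def read_ucihar_layout(
    root, splits: Sequence[str] = ("train", "test"), channels: str = "A"
) -> list[MotionWindow]:
    """Adapt the UCI-HAR directory layout to labeled motion windows.

    Each row of the Inertial Signals files is one pre-segmented 2.56-s
    window (128 samples, 50% overlap).  ``channels='A'`` loads the three
    total-acceleration axes; ``'AG'`` appends the three body-gyroscope axes.
    """
    if channels not in ("A", "AG"):
        raise FormatError(f"channels must be 'A' or 'AG', got {channels!r}")
    root = Path(root)
    names = ["total_acc_x", "total_acc_y", "total_acc_z"]
    if channels == "AG":
        names += ["body_gyro_x", "body_gyro_y", "body_gyro_z"]
    windows: list[MotionWindow] = []
    for split in splits:
        sig_dir = root / split / "Inertial Signals"
        arrays = [_ucihar_signal(sig_dir, n, split) for n in names]
        n_win = arrays[0].shape[0]
        if any(a.shape[0] != n_win for a in arrays):
            raise FormatError(f"{split}: signal files disagree on window count")
        y_file = root / split / f"y_{split}.txt"
        if not y_file.exists():
            raise FormatError(f"missing label file {y_file}")
        labels = np.loadtxt(y_file, dtype=int, ndmin=1)
        if labels.shape[0] != n_win:
            raise FormatError(
                f"{split}: {labels.shape[0]} labels for {n_win} windows"
            )
        subj_file = root / split / f"subject_{split}.txt"
        subjects = (
            np.loadtxt(subj_file, dtype=int, ndmin=1)
            if subj_file.exists()
            else np.zeros(n_win, dtype=int)
        )
        stacked = np.stack(arrays, axis=2)  # (n_win, 128, n_ch)
        for i in range(n_win):
            windows.append(
                MotionWindow(
                    data=stacked[i],
                    class_label=UCIHAR_LABELS[int(labels[i])],
                    subject_id=f"subject{int(subjects[i])}",
                )
            )
    return windows


def write_feature_dataset(ds: AugmentedDataset, path) -> None:
    """Persist an :class:`AugmentedDataset` as versioned CSV.

    Values are written with 17 significant digits so the read/write
    round-trip is bit-for-bit on float64.
    """
    path = Path(path)
    first = ds.samples[0] if len(ds) else None
    columns = list(first.columns) if first is not None else ["SA", "LA", "SG", "LG"]
    with open(path, "w", newline="") as fh:
        fh.write(_FEATURE_MAGIC + "\n")
        fh.write(f"# S={first.S if first else 0} L={first.L if first else 0}\n")
        fh.write(f"# seed={ds.seed if ds.seed is not None else ''}\n")
        fh.write(
            "sample_id,row," + ",".join(columns)
            + ",class_label,intensity_label,provenance,subject_id\n"
        )
        for sid, m in enumerate(ds.samples):
            cls = m.class_label if m.class_label is not None else ""
            inten = repr(float(m.intensity_label)) if m.intensity_label is not None else ""
            subj = m.subject_id if m.subject_id is not None else ""
            for r in range(m.n_rows):
                vals = ",".join(repr(float(v)) for v in m.values[r])
                fh.write(f"{sid},{r},{vals},{cls},{inten},{m.provenance},{subj}\n")


def read_feature_dataset(path) -> AugmentedDataset:
    """Read a versioned feature-dataset CSV written by :func:`write_feature_dataset`."""
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _FEATURE_MAGIC:
            raise FormatError(
                f"{path}: expected header {_FEATURE_MAGIC!r}, found {magic!r}"
            )
        sl_line = fh.readline().rstrip("\n")
        if not sl_line.startswith("# S="):
            raise FormatError(f"{path}: corrupted S/L header line {sl_line!r}")
        parts = dict(p.split("=") for p in sl_line[2:].split())
        S, L = int(parts["S"]), int(parts["L"])
        seed_line = fh.readline().rstrip("\n")
        seed_str = seed_line.split("=", 1)[1] if "=" in seed_line else ""
        seed = int(seed_str) if seed_str else None
        df = pd.read_csv(fh, dtype={"class_label": str, "subject_id": str},
                         float_precision="round_trip")
    samples = []
    if len(df):
        value_cols = [
            c
            for c in df.columns
            if c not in ("sample_id", "row", "class_label", "intensity_label",
                         "provenance", "subject_id")
        ]
        for sid, grp in df.groupby("sample_id", sort=True):
            grp = grp.sort_values("row")
            first = grp.iloc[0]
            cls = first["class_label"]
            subj = first["subject_id"]
            inten = first["intensity_label"]
            samples.append(
                SpectralFeatureMatrix(
                    values=grp[value_cols].to_numpy(dtype=float),
                    S=S,
                    L=L,
                    class_label=None if pd.isna(cls) else str(cls),
                    intensity_label=None if pd.isna(inten) else float(inten),
                    subject_id=None if pd.isna(subj) else str(subj),
                    provenance=str(first["provenance"]),
                    columns=tuple(value_cols),
                )
            )
    return AugmentedDataset(samples=samples, seed=seed)


def write_windows_csv(windows: Sequence[MotionWindow], path) -> None:
    """Persist detected/ground-truth window indices and labels as CSV."""
    rows = [
        {
            "start": w.start,
            "end": w.end,
            "class_label": w.class_label if w.class_label is not None else "",
            "intensity_label": w.intensity_label if w.intensity_label is not None else "",
            "subject_id": w.subject_id if w.subject_id is not None else "",
        }
        for w in windows
    ]
    pd.DataFrame(rows, columns=["start", "end", "class_label", "intensity_label",
                                "subject_id"]).to_csv(path, index=False)


def read_windows_csv(path, recording: Optional[IMURecording] = None) -> list[MotionWindow]:
    """Load windows written by :func:`write_windows_csv`, rebinding a recording."""
    df = pd.read_csv(path, dtype={"class_label": str, "subject_id": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            MotionWindow(
                recording=recording,
                start=int(row["start"]),
                end=int(row["end"]),
                class_label=None if pd.isna(row["class_label"]) else str(row["class_label"]),
                intensity_label=(
                    None if pd.isna(row["intensity_label"]) else float(row["intensity_label"])
                ),
                subject_id=None if pd.isna(row["subject_id"]) else str(row["subject_id"]),
            )
        )
    return out
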