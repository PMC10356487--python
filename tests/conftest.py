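import numpy as np
import pytest

import kicksense as ks


@pytest.fixture(scope="session")
def fixture_data():
    """The tiny deterministic worked fixture: 8 windows, 2 classes."""
    return ks.generate_worked_fixture()


@pytest.fixture(scope="session")
def fixture_features(fixture_data):
    """S = L = 8 spectral feature matrices of the worked fixture windows."""
    _, windows = fixture_data
    cfg = ks.FeatureConfig(S=8, L=8)
    return [ks.extract_features(w, cfg) for w in windows]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(accel, gyro=None, fs=50.0, subject="T01"):
    """Build a validated recording from channel arrays."""
    accel = np.asarray(accel, dtype=float)
    n = accel.shape[0]
    if gyro is None:
        gyro = np.zeros((n, 3))
    return ks.IMURecording(
        subject_id=subject,
        sampling_rate=fs,
        timestamps=np.arange(n) / fs,
        accel=accel,
        gyro=np.asarray(gyro, dtype=float),
        metadata={"accel_units": "m/s^2", "gyro_units": "deg/s"},
    )


def make_feature_matrix(rng, n_rows=8, class_label="a", intensity=1.0,
                        subject="T01"):
    """Random but invariant-respecting spectral feature matrix."""
    cols = []
    for _ in range(2):  # accel pool, gyro pool
        d = np.sort(rng.random(4 * n_rows))
        cols.append(d[:n_rows])          # ascending minima
        cols.append(d[::-1][:n_rows])    # descending maxima
    return ks.SpectralFeatureMatrix(
        values=np.column_stack(cols),
        S=n_rows,
        L=n_rows,
        class_label=class_label,
        intensity_label=intensity,
        subject_id=subject,
    )
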