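"""Shared fixtures: small configurations and synthetic recordings."""

import numpy as np
import pytest

from wbsync import AnalysisConfig
from wbsync.recordings import Recording


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_config():
    """Two narrow bands, coarse grids: fast enough for unit tests."""
    return AnalysisConfig(
        bands=(("theta", 4.0, 8.0), ("alpha", 8.0, 12.0)),
        freq_points_per_band=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(signals, fs=100.0, subject_id="test", labels=None, mask=None):
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(signals.shape[0])]
    return Recording(subject_id=subject_id, signals=signals, fs=fs,
                     channel_labels=labels, mask=mask)


@pytest.fixture
def sinusoid_recording():
    """Two-channel recording: 5 Hz sinusoids with a fixed phase lag."""
    fs = 100.0
    t = np.arange(0, 60.0, 1 / fs)
    x1 = np.sin(2 * np.pi * 5.0 * t)
    x2 = np.sin(2 * np.pi * 5.0 * t + 0.8)
    return make_recording([x1, x2], fs=fs, labels=["C3", "C4"])
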