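"""Shared fixtures: tone traces and a periodogram band-power oracle.

The band-power oracle is a direct discrete-Fourier periodogram integral,
independent of the package's AR-based spectral path, so tests can check
preprocessing and generation against ground truth.
"""
import numpy as np
import pytest
from scipy.signal import periodogram

from beelfp import SignalTrace

FS = 1000.0


@pytest.fixture(scope="session")
def periodogram_band_power():
    def _bp(samples: np.ndarray, lo: float, hi: float, fs: float = FS) -> float:
        f, p = periodogram(samples, fs=fs)
        mask = (f >= lo) & (f <= hi)
        return float(np.trapezoid(p[mask], f[mask]))

    return _bp


@pytest.fixture
def two_tone_trace():
    """25 Hz + 0.7 Hz sinusoids plus a DC offset, 10 s at 1 kHz."""
    t = np.arange(0, 10, 1 / FS)
    samples = 3.0 + np.sin(2 * np.pi * 25 * t) + 2.0 * np.sin(2 * np.pi * 0.7 * t)
    return SignalTrace(samples, FS)


@pytest.fixture
def tone_25hz():
    t = np.arange(0, 10, 1 / FS)
    return SignalTrace(np.sin(2 * np.pi * 25 * t), FS)
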