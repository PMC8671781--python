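"""LFP preprocessing: DC removal and EMD baseline-wander correction.

Optic-lobe recordings carry a DC offset from the electrode interface and a
slow baseline wander (concentrated near 0.7 Hz) from respiration and body
movement of the tethered animal.  The DC component is removed by zeroing
the zero-frequency Fourier coefficient; the wander is removed by empirical
mode decomposition: the trace is split into IMFs, each IMF's mean frequency
is estimated from its zero-crossing rate, and the trace is reconstructed
from the components at or above a cutoff (default 3.5 Hz).  The cutoff sits
well above the 0.7 Hz wander because mode mixing inflates the zero-crossing
frequency of a wander-carrying IMF — riding oscillations add crossings — so
a wander IMF can read several times its true frequency.  The residual trend
is discarded with the sub-cutoff IMFs, since it is the limit case of the
wander.
"""
from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .emd import (
    DEFAULT_MAX_IMFS,
    DEFAULT_STOP_THRESHOLD,
    IMFSet,
    emd,
    imf_mean_frequency,
)
from .traces import SignalTrace

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 3.5


def remove_dc(trace: SignalTrace) -> SignalTrace:
    """Zero the DC (zero-frequency) Fourier component of a trace.

    Implemented as forward FFT, zeroing of bin 0, inverse FFT — which is
    numerically the subtraction of the sample mean.  Length and sampling
    rate are unchanged; the operation is idempotent.
    """
    spectrum = np.fft.rfft(trace.samples)
    spectrum[0] = 0.0
    cleaned = np.fft.irfft(spectrum, n=trace.samples.size)
    return trace.replace_samples(cleaned)


def decompose(
    trace: SignalTrace,
    max_imfs: int = DEFAULT_MAX_IMFS,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
) -> IMFSet:
    """EMD of a trace (thin wrapper binding the trace's sampling rate)."""
    return emd(
        trace.samples,
        sampling_rate=trace.sampling_rate,
        max_imfs=max_imfs,
        stop_threshold=stop_threshold,
    )


def correct_baseline(
    decomp: IMFSet,
    sampling_rate: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Reconstruct a series from the IMFs at or above ``cutoff_hz``.

    IMFs whose zero-crossing mean frequency falls below the cutoff, and the
    residual trend, carry the baseline wander and are dropped.  If every
    component is sub-cutoff the result is the zero series and a warning is
    logged (the cutoff was over-aggressive for this record).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    kept = [
        c for c in decomp.imfs
        if imf_mean_frequency(c, sampling_rate) >= cutoff_hz
    ]
    if not kept:
        logger.warning(
            "baseline correction dropped every component (cutoff %.3g Hz); "
            "returning a zero trace", cutoff_hz,
        )
        return np.zeros(decomp.source_length)
    out = kept[0].copy()
    for c in kept[1:]:
        out += c
    return out


def preprocess_trace(
    trace: SignalTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    max_imfs: int = DEFAULT_MAX_IMFS,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
) -> SignalTrace:
    """Full preprocessing of one trace: DC removal then baseline correction."""
    dc_free = remove_dc(trace)
    decomp = decompose(dc_free, max_imfs=max_imfs, stop_threshold=stop_threshold)
    corrected = correct_baseline(decomp, trace.sampling_rate, cutoff_hz=cutoff_hz)
    # the reconstructed sum of IMFs can carry a tiny residual mean; clear it
    # so downstream AR fitting sees a strictly DC-free trace
    return remove_dc(trace.replace_samples(corrected))


class DCRemover(TransformerMixin, BaseEstimator):
    """Transformer zeroing the DC Fourier component of each row of X.

    X is a 2-D array of shape ``(n_traces, n_samples)``; each row is one
    uniformly sampled trace.  Stateless: ``fit`` only validates input.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_traces, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        spectrum = np.fft.rfft(X, axis=1)
        spectrum[:, 0] = 0.0
        return np.fft.irfft(spectrum, n=X.shape[1], axis=1)


class BaselineWanderCorrector(TransformerMixin, BaseEstimator):
    """Transformer applying EMD baseline correction to each row of X.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate shared by all rows, in Hz.
    cutoff_hz : float
        Components with zero-crossing mean frequency below this are dropped.
    max_imfs, stop_threshold :
        Passed to the sifting loop; see :func:`beelfp.emd.emd`.
    """

    def __init__(
        self,
        sampling_rate: float = 1000.0,
        cutoff_hz: float = DEFAULT_CUTOFF_HZ,
        max_imfs: int = DEFAULT_MAX_IMFS,
        stop_threshold: float = DEFAULT_STOP_THRESHOLD,
    ):
        self.sampling_rate = sampling_rate
        self.cutoff_hz = cutoff_hz
        self.max_imfs = max_imfs
        self.stop_threshold = stop_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_traces, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            decomp = emd(
                row,
                sampling_rate=self.sampling_rate,
                max_imfs=self.max_imfs,
                stop_threshold=self.stop_threshold,
            )
            out[i] = correct_baseline(
                decomp, self.sampling_rate, cutoff_hz=self.cutoff_hz
            )
        return out
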