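"""Burg autoregressive spectral estimation.

The Burg method fits an AR(p) model to a trace by minimizing the summed
forward and backward prediction-error power through a lattice recursion,
which guarantees reflection coefficients of magnitude at most one and hence
a stable spectrum — well suited to short LFP records where periodogram
variance would swamp the 20–30 Hz structure of interest.

Coefficient convention used throughout:  x_t + sum_k a_k x_{t-k} = e_t,
so the AR transfer denominator is A(z) = 1 + sum_k a_k z^{-k} and the
one-sided PSD is  P(f) = 2 * (sigma^2 / fs) / |A(e^{-i 2 pi f / fs})|^2
at interior frequencies (no doubling at 0 and Nyquist).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import SignalTrace

logger = logging.getLogger(__name__)

DEFAULT_ORDER = 15
DEFAULT_NFFT = 1024


@dataclass
class ARModel:
    """Burg-estimated AR model.

    ``coefficients`` are a_1..a_p in the convention
    x_t + sum_k a_k x_{t-k} = e_t; ``noise_variance`` is the final
    prediction-error power; ``reflection_coefficients`` are the lattice
    k_m values (all of magnitude <= 1 for a valid Burg fit).
    """

    order: int
    coefficients: np.ndarray
    noise_variance: float
    sampling_rate: float
    reflection_coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.reflection_coefficients = np.asarray(
            self.reflection_coefficients, dtype=float
        )
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.coefficients.size != self.order:
            raise ValueError("need exactly `order` coefficients")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")

    @property
    def is_stable(self) -> bool:
        if self.reflection_coefficients.size == 0:
            return True
        return bool(np.all(np.abs(self.reflection_coefficients) <= 1.0 + 1e-12))


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a fixed frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    nfft: int
    source_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency grid and power must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class AveragePSD:
    """Pointwise mean PSD over several records with per-frequency error."""

    frequencies: np.ndarray
    mean_power: np.ndarray
    error: np.ndarray
    n_samples: int
    error_kind: str = "SD"


def burg_ar(trace: SignalTrace | np.ndarray, order: int = DEFAULT_ORDER,
            sampling_rate: float | None = None) -> ARModel:
    """Fit an AR model by the Burg lattice recursion.

    Forward and backward prediction errors are initialized to the signal;
    at stage m the reflection coefficient

        k_m = -2 sum_t f(t) b(t-1) / sum_t (f(t)^2 + b(t-1)^2)

    feeds a Levinson update of the coefficients and the lattice update of
    the errors.  The driving-noise variance starts at the signal power and
    shrinks by (1 - k_m^2) per stage.

    Accepts a :class:`SignalTrace` or a bare array (``sampling_rate``
    required in the latter case).  The trace should already be DC-free;
    a residual mean above 1e-6 of the RMS triggers a warning.
    """
    if isinstance(trace, SignalTrace):
        x = trace.samples
        fs = trace.sampling_rate
    else:
        x = np.asarray(trace, dtype=float)
        fs = float(sampling_rate) if sampling_rate is not None else 1.0
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= order:
        raise ValueError(f"trace length {n} must exceed order {order}")

    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0 and abs(float(np.mean(x))) > 1e-6 * rms:
        warnings.warn(
            "trace is not DC-free; remove the DC component before Burg fitting",
            stacklevel=2,
        )
    if rms == 0.0:
        return ARModel(order=order, coefficients=np.zeros(order),
                       noise_variance=0.0, sampling_rate=fs,
                       reflection_coefficients=np.zeros(order))

    f = x.astype(float).copy()   # forward errors, valid at indices m..n-1
    b = x.astype(float).copy()   # backward errors, b[t] valid at m-1..n-1
    a = np.zeros(order + 1)
    a[0] = 1.0
    e = float(np.mean(x**2))
    ks = np.zeros(order)
    for m in range(1, order + 1):
        fseg = f[m:]
        bseg = b[m - 1:n - 1]
        den = float(np.dot(fseg, fseg) + np.dot(bseg, bseg))
        k = 0.0 if den == 0.0 else -2.0 * float(np.dot(fseg, bseg)) / den
        ks[m - 1] = k
        a[1:m + 1] = a[1:m + 1] + k * a[m - 1::-1]
        f_new = fseg + k * bseg
        b[m:] = bseg + k * fseg
        f[m:] = f_new
        e *= (1.0 - k * k)
    return ARModel(order=order, coefficients=a[1:], noise_variance=e,
                   sampling_rate=fs, reflection_coefficients=ks)


def ar_psd(model: ARModel, nfft: int = DEFAULT_NFFT) -> PSDEstimate:
    """Evaluate the one-sided AR power spectrum on an nfft-point DFT grid.

    The grid is f_j = j * fs / nfft for j = 0..nfft/2 (nfft/2 + 1 points
    spanning [0, fs/2]); interior bins are doubled for the one-sided form.
    """
    if nfft < 2 * max(model.order, 1):
        raise ValueError("nfft must be at least twice the model order")
    if nfft & (nfft - 1) != 0:
        warnings.warn("nfft is not a power of two; DFT grid is still valid",
                      stacklevel=2)
    if not model.is_stable:
        raise ValueError(
            "model has a reflection coefficient of magnitude > 1; "
            "refusing to evaluate an unstable spectrum"
        )
    poly = np.zeros(nfft)
    poly[0] = 1.0
    poly[1:model.order + 1] = model.coefficients
    denom = np.abs(np.fft.rfft(poly)[: nfft // 2 + 1]) ** 2
    fs = model.sampling_rate
    power = (model.noise_variance / fs) / denom
    power[1:-1] *= 2.0
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    return PSDEstimate(frequencies=freqs, power=power, nfft=nfft,
                       source_meta={"order": model.order})


def estimate_psd(trace: SignalTrace, order: int = DEFAULT_ORDER,
                 nfft: int = DEFAULT_NFFT) -> PSDEstimate:
    """Burg AR fit followed by spectrum evaluation, for one trace."""
    psd = ar_psd(burg_ar(trace, order=order), nfft=nfft)
    psd.source_meta.update({"state_label": trace.state_label, **trace.meta})
    return psd


def average_psd(estimates: list[PSDEstimate], error_kind: str = "SD") -> AveragePSD:
    """Pointwise mean of several PSDs with per-frequency SD or SEM.

    All estimates must share one frequency grid.  ``error_kind`` selects
    the sample standard deviation (n-1 denominator) or the standard error
    of the mean; with a single estimate the error is zero.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if error_kind not in ("SD", "SEM"):
        raise ValueError("error_kind must be 'SD' or 'SEM'")
    grid = estimates[0].frequencies
    for est in estimates[1:]:
        if est.frequencies.shape != grid.shape or not np.allclose(
            est.frequencies, grid
        ):
            raise ValueError("all estimates must share one frequency grid")
    stack = np.vstack([est.power for est in estimates])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    err = sd / np.sqrt(n) if error_kind == "SEM" else sd
    return AveragePSD(frequencies=grid, mean_power=mean, error=err,
                      n_samples=n, error_kind=error_kind)


class BurgSpectrum(TransformerMixin, BaseEstimator):
    """Transformer mapping traces (rows of X) to one-sided Burg PSDs.

    Output has shape ``(n_traces, nfft // 2 + 1)``; the shared frequency
    grid is exposed as ``frequencies_`` after ``fit``.
    """

    def __init__(self, sampling_rate: float = 1000.0,
                 order: int = DEFAULT_ORDER, nfft: int = DEFAULT_NFFT):
        self.sampling_rate = sampling_rate
        self.order = order
        self.nfft = nfft

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_traces, n_samples)")
        if X.shape[1] <= self.order:
            raise ValueError("traces must be longer than the AR order")
        self.n_features_in_ = X.shape[1]
        self.frequencies_ = (
            np.arange(self.nfft // 2 + 1) * self.sampling_rate / self.nfft
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.nfft // 2 + 1))
        for i, row in enumerate(X):
            model = burg_ar(row, order=self.order,
                            sampling_rate=self.sampling_rate)
            out[i] = ar_psd(model, nfft=self.nfft).power
        return out
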