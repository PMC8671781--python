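"""Spectral features separating flapping from calm-state LFP spectra.

Flapping-state optic-lobe spectra differ from calm ones in three ways: a
power peak in the 20–30 Hz band, elevated power below 15 Hz, and a more
fluctuating curve below 50 Hz.  This module turns those cues into numbers
(band power, peak prominence, a fluctuation count) and into a deterministic
state call, and locates the transition frequency — the lowest frequency at
which the average flapping PSD drops below the average calm PSD.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .spectral import AveragePSD, PSDEstimate

logger = logging.getLogger(__name__)

FLAP_BAND = (20.0, 30.0)
LOW_BAND = (0.0, 15.0)
FLUCTUATION_MAX_HZ = 50.0

#: Default decision thresholds: minimum in-band peak prominence, minimum
#: fluctuation count, and minimum low-band power ratio against a calm
#: reference.  The rule calls "flapping" iff a sufficiently prominent
#: 20–30 Hz peak exists AND (the curve fluctuates enough OR low-band power
#: is elevated over the reference).
DEFAULT_THRESHOLDS = {
    "peak_prominence_min": 1.5,
    "fluctuation_min": 3,
    "lowband_ratio_min": 1.3,
}


@dataclass
class SpectralFeatures:
    """Feature vector extracted from one PSD."""

    lowband_power: float
    flapband_peak_freq: float | None
    flapband_peak_prominence: float | None
    fluctuation_score: int
    state_call: str | None = None


def band_power(psd: PSDEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] Hz (units µV²).

    Band edges may fall between grid points; power there is linearly
    interpolated so the integral is additive over adjacent bands.
    """
    f, p = psd.frequencies, psd.power
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    if lo < f[0] or hi > f[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside the grid [{f[0]}, {f[-1]}] Hz"
        )
    grid = np.concatenate(([lo], f[(f > lo) & (f < hi)], [hi]))
    values = np.interp(grid, f, p)
    return float(np.trapezoid(values, grid))


def _strict_local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima; plateaus break toward the
    lower-frequency edge."""
    d = np.sign(np.diff(p))
    # backward-fill zero slopes with the next nonzero slope so a plateau's
    # low-frequency edge is the turning point
    rev = d[::-1]
    last = np.maximum.accumulate(np.where(rev != 0, np.arange(rev.size), -1))
    bf = np.where(last >= 0, rev[np.maximum(last, 0)], 0)[::-1]
    rising = np.concatenate(([False], d > 0))
    falling = np.concatenate((bf < 0, [False]))
    return np.flatnonzero(rising & falling)


def detect_flapband_peak(
    psd: PSDEstimate, band: tuple[float, float] = FLAP_BAND
) -> tuple[float, float] | None:
    """Highest strict local maximum of power inside ``band``.

    Returns ``(frequency_hz, prominence)`` where prominence is the peak
    power divided by the median in-band power, or ``None`` when no strict
    interior maximum lies in the band.
    """
    f, p = psd.frequencies, psd.power
    lo, hi = band
    if lo < f[0] or hi > f[-1]:
        raise ValueError("band outside the frequency grid")
    peaks = _strict_local_maxima(p)
    in_band = peaks[(f[peaks] >= lo) & (f[peaks] <= hi)]
    if in_band.size == 0:
        return None
    best = in_band[np.argmax(p[in_band])]
    band_mask = (f >= lo) & (f <= hi)
    med = float(np.median(p[band_mask]))
    prominence = float(p[best] / med) if med > 0 else np.inf
    return float(f[best]), prominence


def fluctuation_score(psd: PSDEstimate, max_hz: float = FLUCTUATION_MAX_HZ) -> int:
    """Count of strict local maxima of log-power below ``max_hz``."""
    mask = psd.frequencies < max_hz
    logp = np.log(np.maximum(psd.power[mask], np.finfo(float).tiny))
    return int(_strict_local_maxima(logp).size)


def extract_features(
    psd: PSDEstimate,
    band: tuple[float, float] = FLAP_BAND,
    low_band: tuple[float, float] = LOW_BAND,
) -> SpectralFeatures:
    """Compute the full feature vector (without a state call) for one PSD."""
    peak = detect_flapband_peak(psd, band=band)
    return SpectralFeatures(
        lowband_power=band_power(psd, *low_band),
        flapband_peak_freq=None if peak is None else peak[0],
        flapband_peak_prominence=None if peak is None else peak[1],
        fluctuation_score=fluctuation_score(psd),
    )


def classify_state(
    features: SpectralFeatures,
    thresholds: dict | None = None,
    calm_reference_lowband: float | None = None,
) -> str:
    """Deterministic flapping/calm call from one feature vector.

    ``"flapping"`` iff a 20–30 Hz peak exists with prominence >=
    ``peak_prominence_min`` AND (fluctuation_score >= ``fluctuation_min``
    OR lowband_power / calm_reference_lowband >= ``lowband_ratio_min``).
    The low-band ratio clause requires a calm reference power; omitting it
    disables that clause only if the fluctuation clause can still decide —
    otherwise it is a configuration error.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    use_ratio = th.get("lowband_ratio_min") is not None
    if use_ratio and calm_reference_lowband is None:
        raise ValueError(
            "the low-band ratio clause needs calm_reference_lowband; "
            "pass it or set thresholds['lowband_ratio_min'] = None"
        )
    peak_ok = (
        features.flapband_peak_prominence is not None
        and features.flapband_peak_prominence >= th["peak_prominence_min"]
    )
    fluct_ok = features.fluctuation_score >= th["fluctuation_min"]
    ratio_ok = False
    if use_ratio and calm_reference_lowband and calm_reference_lowband > 0:
        ratio_ok = (
            features.lowband_power / calm_reference_lowband
            >= th["lowband_ratio_min"]
        )
    call = "flapping" if (peak_ok and (fluct_ok or ratio_ok)) else "calm"
    logger.info(
        "state call %s: peak_ok=%s fluct_ok=%s ratio_ok=%s thresholds=%s",
        call, peak_ok, fluct_ok, ratio_ok, th,
    )
    return call


def find_transition_frequency(
    flap: AveragePSD, calm: AveragePSD
) -> float | None:
    """Lowest frequency where the flap-minus-calm mean PSD turns negative.

    The crossing is located by linear interpolation between the bracketing
    grid points; returns ``None`` when the difference never changes sign
    from positive to negative.
    """
    if flap.frequencies.shape != calm.frequencies.shape or not np.allclose(
        flap.frequencies, calm.frequencies
    ):
        raise ValueError("average PSDs must share one frequency grid")
    f = flap.frequencies
    d = flap.mean_power - calm.mean_power
    pos_to_neg = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0))
    exact = np.flatnonzero((d[:-1] > 0) & (d[1:] == 0))
    candidates = []
    for i in pos_to_neg:
        candidates.append(f[i] + (f[i + 1] - f[i]) * d[i] / (d[i] - d[i + 1]))
    for i in exact:
        candidates.append(float(f[i + 1]))
    if not candidates:
        return None
    return float(min(candidates))


class FlightStateClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based flapping/calm classifier over PSD rows.

    X rows are one-sided PSD vectors on the grid given by ``frequencies``
    (or set at ``fit`` time from ``sampling_rate`` and ``nfft``).  ``fit``
    learns the calm low-band reference power as the mean 0–15 Hz power of
    the calm-labeled training rows; ``predict`` applies the thresholded
    peak/fluctuation/low-band rule.
    """

    def __init__(
        self,
        sampling_rate: float = 1000.0,
        nfft: int = 1024,
        band: tuple[float, float] = FLAP_BAND,
        low_band: tuple[float, float] = LOW_BAND,
        peak_prominence_min: float = DEFAULT_THRESHOLDS["peak_prominence_min"],
        fluctuation_min: int = DEFAULT_THRESHOLDS["fluctuation_min"],
        lowband_ratio_min: float | None = DEFAULT_THRESHOLDS["lowband_ratio_min"],
    ):
        self.sampling_rate = sampling_rate
        self.nfft = nfft
        self.band = band
        self.low_band = low_band
        self.peak_prominence_min = peak_prominence_min
        self.fluctuation_min = fluctuation_min
        self.lowband_ratio_min = lowband_ratio_min

    def _grid(self) -> np.ndarray:
        return np.arange(self.nfft // 2 + 1) * self.sampling_rate / self.nfft

    def _psd(self, row: np.ndarray) -> PSDEstimate:
        return PSDEstimate(frequencies=self._grid(), power=row, nfft=self.nfft)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.nfft // 2 + 1:
            raise ValueError("X rows must be one-sided PSDs of nfft/2 + 1 bins")
        self.classes_ = np.array(["calm", "flapping"])
        calm_rows = X[y == "calm"]
        if calm_rows.size:
            self.calm_lowband_reference_ = float(
                np.mean([
                    band_power(self._psd(r), *self.low_band) for r in calm_rows
                ])
            )
        elif self.lowband_ratio_min is None:
            self.calm_lowband_reference_ = None
        else:
            raise ValueError(
                "no calm-labeled rows to learn the low-band reference; "
                "set lowband_ratio_min=None to disable that clause"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "calm_lowband_reference_")
        X = np.asarray(X, dtype=float)
        th = {
            "peak_prominence_min": self.peak_prominence_min,
            "fluctuation_min": self.fluctuation_min,
            "lowband_ratio_min": self.lowband_ratio_min,
        }
        calls = []
        for row in X:
            feats = extract_features(
                self._psd(row), band=self.band, low_band=self.low_band
            )
            calls.append(
                classify_state(
                    feats, thresholds=th,
                    calm_reference_lowband=self.calm_lowband_reference_,
                )
            )
        return np.asarray(calls)
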