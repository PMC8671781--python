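"""Empirical mode decomposition by sifting.

EMD splits a signal into intrinsic mode functions (IMFs) ordered from high
to low frequency plus a residual trend, using only the signal's own extrema:
each sifting pass interpolates cubic-spline envelopes through the local
maxima and minima and subtracts their mean until the candidate satisfies the
IMF definition (extrema and zero-crossing counts differ by at most one, and
the envelope mean is small).  The decomposition is complete by construction:
the IMFs and residue sum back to the input exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: Cauchy-type sifting stop threshold: sifting ends once the normalized
#: squared successive difference sum((h_prev - h)^2) / sum(h_prev^2) falls
#: below this value and the candidate meets the IMF extrema criterion.
DEFAULT_STOP_THRESHOLD = 0.2
DEFAULT_MAX_IMFS = 12
_MAX_SIFTS = 200
_N_MIRROR = 2  # extrema reflected past each end before spline fitting


@dataclass
class IMFSet:
    """Ordered IMFs (highest frequency first) plus the residual trend."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        for c in self.imfs:
            if len(c) != self.source_length:
                raise ValueError("every IMF must match the source length")
        if len(self.residue) != self.source_length:
            raise ValueError("residue must match the source length")

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residue (equals the input signal)."""
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of ``x``.

    Plateaus are collapsed: a flat stretch bounded by opposite slopes
    contributes a single extremum at its last sample, which keeps the
    detection deterministic on quantized data.
    """
    x = np.asarray(x, dtype=float)
    d = np.sign(np.diff(x))
    nz = np.flatnonzero(d)
    if nz.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # forward-fill zero slopes with the previous nonzero slope
    filled = d.copy()
    last = np.maximum.accumulate(np.where(d != 0, np.arange(d.size), -1))
    valid = last >= 0
    filled[valid] = d[last[valid]]
    turn = np.diff(filled)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def count_zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def imf_mean_frequency(imf: np.ndarray, sampling_rate: float) -> float:
    """Zero-crossing-rate frequency estimate of one component, in Hz.

    Half the zero-crossing count divided by the spanned duration
    ``(n - 1) / sampling_rate``; a constant series maps to 0 Hz.
    """
    imf = np.asarray(imf, dtype=float)
    if imf.size < 2:
        raise ValueError("need at least two samples")
    duration = (imf.size - 1) / sampling_rate
    return (count_zero_crossings(imf) / 2.0) / duration


def _envelope(x: np.ndarray, idx: np.ndarray, values: np.ndarray,
              kind: str) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends.

    Up to ``_N_MIRROR`` extrema are reflected about the first and last
    sample so the spline brackets the full support.  When an endpoint
    overshoots the nearest extremum (signal rising past the last maximum,
    say) the mirrored knots cannot bracket it and the spline would swing
    wildly; in that case the endpoint itself is promoted to an extremum
    before mirroring.  Falls back to linear interpolation when fewer than
    four knots are available.
    """
    n = x.size
    sign = 1.0 if kind == "max" else -1.0
    if idx[0] != 0 and sign * x[0] > sign * values[0]:
        idx = np.concatenate(([0], idx))
        values = np.concatenate(([x[0]], values))
    if idx[-1] != n - 1 and sign * x[-1] > sign * values[-1]:
        idx = np.concatenate((idx, [n - 1]))
        values = np.concatenate((values, [x[-1]]))
    k = min(_N_MIRROR, idx.size)
    left_i = (2 * 0 - idx[:k])[::-1]
    left_v = values[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = values[-k:][::-1]
    knots_i = np.concatenate([left_i, idx, right_i]).astype(float)
    knots_v = np.concatenate([left_v, values, right_v])
    knots_i, uniq = np.unique(knots_i, return_index=True)
    knots_v = knots_v[uniq]
    t = np.arange(n, dtype=float)
    if knots_i.size < 4:
        return np.interp(t, knots_i, knots_v)
    return CubicSpline(knots_i, knots_v)(t)


def _sift_once(h: np.ndarray) -> np.ndarray | None:
    """One sifting pass: subtract the mean of the two spline envelopes.

    Returns the new candidate, or ``None`` when too few extrema remain to
    build both envelopes.
    """
    maxima, minima = local_extrema(h)
    if maxima.size + minima.size <= 2 or maxima.size < 1 or minima.size < 1:
        return None
    upper = _envelope(h, maxima, h[maxima], "max")
    lower = _envelope(h, minima, h[minima], "min")
    return h - 0.5 * (upper + lower)


def _is_imf(h: np.ndarray) -> bool:
    maxima, minima = local_extrema(h)
    return abs((maxima.size + minima.size) - count_zero_crossings(h)) <= 1


def emd(
    samples: np.ndarray,
    sampling_rate: float = 1.0,
    max_imfs: int = DEFAULT_MAX_IMFS,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
) -> IMFSet:
    """Decompose a series into intrinsic mode functions plus a residue.

    Parameters
    ----------
    samples : array-like
        The series to decompose; length >= 4.
    sampling_rate : float
        Only recorded for downstream frequency bookkeeping; the sifting
        itself is rate-agnostic.
    max_imfs : int
        Upper bound on extracted IMFs; guards against over-decomposition
        of long noisy records.
    stop_threshold : float
        Cauchy-type normalized squared successive-difference threshold for
        ending a sift (default 0.2).

    Returns
    -------
    IMFSet
        IMFs from highest to lowest frequency and the residual trend.
        A series with fewer than three extrema yields zero IMFs and
        ``residue == samples``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("emd needs a 1-D series of length >= 4")
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    # residue is subtracted from a running copy so completeness is exact
    while len(imfs) < max_imfs:
        maxima, minima = local_extrema(residue)
        if maxima.size + minima.size < 3:
            break  # monotone or near-monotone trend: stop
        h = residue.copy()
        for _ in range(_MAX_SIFTS):
            h_new = _sift_once(h)
            if h_new is None:
                break
            denom = float(np.dot(h, h))
            sd = float(np.dot(h - h_new, h - h_new)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop_threshold and _is_imf(h):
                break
        if not _is_imf(h):
            # extremely rare with the sift budget above; keep the component
            # (discarding it would corrupt the reconstruction) but flag it
            logger.warning(
                "IMF %d did not reach the extrema/zero-crossing criterion "
                "within %d sifts", len(imfs) + 1, _MAX_SIFTS,
            )
        imfs.append(h)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue, source_length=x.size)
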