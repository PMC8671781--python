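"""Stimulation-response statistics.

Aggregates screening trials into the flight-initiation success-rate table
over the (stimulation frequency, voltage amplitude) grid, narrows the grid
to the region reaching a success criterion (80% by default), and summarizes
the flapping-frequency / flapping-duration responses of initiated trials
(means, SDs, Pearson correlation, covariance).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrialRecord

REFINE_CRITERION = 0.8


@dataclass
class SuccessRateTable:
    """Per-cell flight-initiation rates over the stimulation grid.

    ``rates`` and ``counts`` are DataFrames indexed by stimulation
    frequency (Hz) with voltage amplitudes (V) as columns; cells with no
    trials are NaN in ``rates`` and 0 in ``counts``.
    """

    rates: pd.DataFrame
    counts: pd.DataFrame

    @property
    def frequencies(self) -> np.ndarray:
        return self.rates.index.to_numpy()

    @property
    def voltages(self) -> np.ndarray:
        return self.rates.columns.to_numpy()

    def max_rate(self) -> tuple[float, float, float]:
        """(P, frequency, voltage) of the best-performing populated cell."""
        stacked = self.rates.stack()
        (f, u) = stacked.idxmax()
        return float(stacked.max()), float(f), float(u)


@dataclass
class BehaviorSummary:
    """Summary statistics of initiated-trial responses."""

    n: int
    dur_mean: float
    dur_sd: float
    freq_mean: float
    freq_sd: float
    pearson_r: float
    covariance: float


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame with the canonical column names."""
    return pd.DataFrame({
        "stim_freq_hz": [t.stim_freq for t in trials],
        "stim_voltage_v": [t.stim_voltage for t in trials],
        "duty_ratio": [t.duty_ratio for t in trials],
        "polarity": [t.polarity for t in trials],
        "stim_duration_s": [t.stim_duration for t in trials],
        "initiated": [t.initiated for t in trials],
        "flap_freq_hz": [t.flap_freq for t in trials],
        "flap_dur_ms": [t.flap_dur for t in trials],
    })


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(list(trials))


def success_rate_table(trials) -> SuccessRateTable:
    """Group trials by exact (F, U) and compute initiation rates.

    Accepts a list of :class:`TrialRecord` or an equivalent DataFrame.
    """
    frame = _as_frame(trials)
    if frame.empty:
        raise ValueError("need at least one trial")
    grouped = frame.groupby(["stim_freq_hz", "stim_voltage_v"])["initiated"]
    rates = grouped.mean().unstack()
    counts = grouped.size().unstack().fillna(0).astype(int)
    rates = rates.sort_index().sort_index(axis=1)
    counts = counts.reindex(index=rates.index, columns=rates.columns).fillna(0)
    return SuccessRateTable(rates=rates, counts=counts.astype(int))


def refine_grid(
    table: SuccessRateTable, criterion: float = REFINE_CRITERION
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Minimal contiguous (frequency range, voltage range) covering all
    cells with P >= criterion; ``None`` when no cell qualifies."""
    mask = table.rates.to_numpy() >= criterion
    mask &= ~np.isnan(table.rates.to_numpy())
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    freqs = table.frequencies
    volts = table.voltages
    return (
        (float(freqs[rows[0]]), float(freqs[rows[-1]])),
        (float(volts[cols[0]]), float(volts[cols[-1]])),
    )


def summarize_flight(trials) -> BehaviorSummary:
    """Means, SDs, Pearson r and covariance of initiated-trial responses.

    Only trials with both flapping frequency and duration present enter;
    SDs and the covariance use the n-1 denominator.  Raises when fewer
    than two complete response pairs exist.
    """
    frame = _as_frame(trials)
    done = frame[frame["initiated"].astype(bool)].dropna(
        subset=["flap_freq_hz", "flap_dur_ms"]
    )
    if len(done) < 2:
        raise ValueError("need at least two initiated trials with responses")
    freq = done["flap_freq_hz"].to_numpy(dtype=float)
    dur = done["flap_dur_ms"].to_numpy(dtype=float)
    cov = float(np.cov(dur, freq, ddof=1)[0, 1])
    r = float(np.corrcoef(dur, freq)[0, 1])
    return BehaviorSummary(
        n=len(done),
        dur_mean=float(dur.mean()),
        dur_sd=float(dur.std(ddof=1)),
        freq_mean=float(freq.mean()),
        freq_sd=float(freq.std(ddof=1)),
        pearson_r=r,
        covariance=cov,
    )
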