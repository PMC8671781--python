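"""Containers for single-channel LFP recordings.

A recording is a uniformly sampled voltage series from one optic-lobe
electrode, tagged with its sampling rate and (when known) the behavioral
state of the animal at recording time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

VALID_STATES = ("flapping", "calm", "unknown")


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage values in microvolts, one per sample.
    sampling_rate : float
        Samples per second (Hz).
    state_label : str
        Behavioral state during the recording: ``"flapping"``, ``"calm"``
        or ``"unknown"``.
    meta : dict
        Free-form provenance (seed, source file, generator config echo).
    """

    samples: np.ndarray
    sampling_rate: float
    state_label: str = "unknown"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.state_label not in VALID_STATES:
            raise ValueError(
                f"state_label must be one of {VALID_STATES}, got {self.state_label!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Span between the first and last sample, in seconds."""
        return (self.samples.size - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "SignalTrace":
        """New trace with the same rate/label/meta but different samples."""
        return SignalTrace(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            state_label=self.state_label,
            meta=dict(self.meta),
        )
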