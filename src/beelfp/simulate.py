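"""Synthetic honeybee optic-lobe LFP traces and stimulation-trial tables.

The LFP generator emulates the statistical structure the analysis pipeline
assumes from tethered-honeybee recordings: an electrode DC offset, slow
baseline wander concentrated near 0.7 Hz, 1/f-shaped broadband background,
and — in the flapping state — a 20–30 Hz oscillation plus a redistribution
of background power toward the 0–15 Hz band (boost below 15 Hz, mild
attenuation above), so that flapping and calm spectra cross at a transition
frequency.

The behavioral generator emulates stimulation screening: per-cell Bernoulli
flight initiation with a log-Gaussian success surface peaking near 60 Hz /
7 V, and, for initiated trials, a flapping frequency (Gaussian) and flapping
duration (lognormal, SD comparable to its mean) coupled by a Gaussian copula
calibrated in closed form to the target Pearson correlation of -0.35.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .traces import SignalTrace


@dataclass
class LfpGenConfig:
    """Parameters of the synthetic LFP generator (amplitudes in µV)."""

    sampling_rate: float = 1000.0
    duration_s: float = 10.0
    dc_offset: float = 20.0
    baseline_freq: float = 0.7
    baseline_amp: float = 100.0
    background_spectral_exponent: float = 1.0
    background_amp: float = 20.0
    flap_band: tuple[float, float] = (20.0, 30.0)
    flap_osc_amp: float = 60.0
    lowband_boost: float = 4.0
    highband_atten: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate and duration_s must be positive")
        if self.sampling_rate <= 2 * self.flap_band[1]:
            raise ValueError("sampling_rate must exceed twice the flap band top")
        if not (0 < self.flap_band[0] < self.flap_band[1]):
            raise ValueError("flap_band must satisfy 0 < lo < hi")
        for name in ("baseline_amp", "background_amp", "flap_osc_amp",
                     "lowband_boost", "highband_atten"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BehaviorGenConfig:
    """Parameters of the synthetic stimulation-trial generator.

    Defaults reproduce the refined screening grid (F in {3..100} Hz,
    U in {3..8} V), a success surface peaking at 60 Hz / 7 V with top
    probability 0.85, and flapping-response marginals of 120.657 Hz
    (SD 20.225) and 448.143 ms (SD 411.659) with Pearson correlation
    -0.35 between duration and frequency.
    """

    grid_frequencies: tuple[float, ...] = (3.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    grid_voltages: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    freq_opt: float = 60.0
    voltage_opt: float = 7.0
    peak_probability: float = 0.85
    log_freq_width: float = 1.0
    log_voltage_width: float = 0.4
    freq_mean: float = 120.657
    freq_sd: float = 20.225
    dur_mean: float = 448.143
    dur_sd: float = 411.659
    dur_freq_corr: float = -0.35
    duty_ratio: float = 0.4
    polarity: str = "bipolar"
    stim_duration_s: float = 0.4
    trials_per_cell: int = 8
    seed: int = 0

    def validate(self) -> None:
        if not self.grid_frequencies or not self.grid_voltages:
            raise ValueError("stimulation grid must be non-empty")
        if not (0.0 <= self.peak_probability <= 1.0):
            raise ValueError("peak_probability must lie in [0, 1]")
        if not (-1.0 <= self.dur_freq_corr <= 1.0):
            raise ValueError("dur_freq_corr must lie in [-1, 1]")
        if self.freq_sd <= 0 or self.dur_sd <= 0:
            raise ValueError("marginal SDs must be positive")
        if not (0.0 < self.duty_ratio < 1.0):
            raise ValueError("duty_ratio must lie in (0, 1)")
        if self.trials_per_cell < 0:
            raise ValueError("trials_per_cell must be >= 0")


@dataclass
class TrialRecord:
    """One stimulation trial and its behavioral outcome."""

    stim_freq: float
    stim_voltage: float
    duty_ratio: float
    polarity: str
    stim_duration: float
    initiated: bool
    flap_freq: float | None = None
    flap_dur: float | None = None
    deflection_angle: float | None = None

    def __post_init__(self) -> None:
        if not self.initiated and (
            self.flap_freq is not None or self.flap_dur is not None
        ):
            raise ValueError("non-initiated trials cannot carry responses")
        if not (0.0 < self.duty_ratio < 1.0):
            raise ValueError("duty_ratio must lie in (0, 1)")
        if self.stim_freq <= 0 or self.stim_voltage <= 0 or self.stim_duration <= 0:
            raise ValueError("stimulus parameters must be positive")


def _shaped_background(rng: np.random.Generator, n: int, fs: float,
                       exponent: float, amp_rms: float) -> np.ndarray:
    """Gaussian noise spectrally shaped as 1/f^exponent, scaled to amp_rms.

    The 1/f gain is clamped below 0.1 Hz so the DC-adjacent bins stay
    finite; the realization is rescaled to the requested sample RMS.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / np.maximum(freqs, 0.1) ** (exponent / 2.0)
    gain[0] = 0.0  # no DC in the background; the offset is a separate term
    shaped = np.fft.irfft(spec * gain, n=n)
    rms = float(np.sqrt(np.mean(shaped**2)))
    if rms > 0:
        shaped *= amp_rms / rms
    return shaped


def _flap_band_rescale(x: np.ndarray, fs: float, split_hz: float,
                       low_gain: float, high_gain: float) -> np.ndarray:
    """Scale power below/above ``split_hz`` by ``low_gain``/``high_gain``."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    scale = np.where(freqs <= split_hz, math.sqrt(low_gain), math.sqrt(high_gain))
    return np.fft.irfft(spec * scale, n=x.size)


def generate_lfp(config: LfpGenConfig, state: str) -> SignalTrace:
    """Generate one synthetic LFP trace in the given behavioral state.

    The trace is the sum of the DC offset, the baseline wander (a 0.7 Hz
    sinusoid with random phase plus a small random-walk drift), the shaped
    background, and — in the flapping state — a frequency-modulated
    oscillation whose instantaneous frequency stays inside ``flap_band``.
    In the flapping state the background is additionally rescaled: power
    below 15 Hz multiplied by ``lowband_boost``, power above by
    ``highband_atten``.  Identical (config, state) pairs give bit-identical
    traces.
    """
    config.validate()
    if state not in ("flapping", "calm"):
        raise ValueError("state must be 'flapping' or 'calm'")
    rng = np.random.default_rng([config.seed, 1 if state == "flapping" else 0])
    fs = config.sampling_rate
    n = int(round(fs * config.duration_s))
    t = np.arange(n) / fs

    phase = rng.uniform(0.0, 2.0 * np.pi)
    wander = config.baseline_amp * np.sin(
        2.0 * np.pi * config.baseline_freq * t + phase
    )
    walk = np.cumsum(rng.standard_normal(n))
    walk -= walk.mean()
    walk_rms = float(np.sqrt(np.mean(walk**2)))
    if walk_rms > 0:
        walk *= 0.15 * config.baseline_amp / walk_rms

    background = _shaped_background(
        rng, n, fs, config.background_spectral_exponent, config.background_amp
    )
    osc = np.zeros(n)
    if state == "flapping":
        background = _flap_band_rescale(
            background, fs, split_hz=15.0,
            low_gain=config.lowband_boost, high_gain=config.highband_atten,
        )
        lo, hi = config.flap_band
        center = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
        fm_phase = rng.uniform(0.0, 2.0 * np.pi)
        depth = 0.15 * (hi - lo)
        f_inst = np.clip(
            center + depth * np.sin(2.0 * np.pi * 0.2 * t + fm_phase), lo, hi
        )
        osc_phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
        osc = config.flap_osc_amp * np.sin(osc_phase)

    samples = config.dc_offset + wander + walk + background + osc
    return SignalTrace(
        samples=samples, sampling_rate=fs, state_label=state,
        meta={"seed": config.seed, "generator": "synthetic-lfp",
              "config": asdict(config)},
    )


def success_probability(config: BehaviorGenConfig, stim_freq: float,
                        stim_voltage: float) -> float:
    """Flight-initiation probability at one (F, U) stimulation point.

    A separable product of Gaussian bumps in log-frequency and log-voltage,
    maximized at (freq_opt, voltage_opt) with value ``peak_probability``.
    """
    zf = math.log(stim_freq / config.freq_opt) / config.log_freq_width
    zu = math.log(stim_voltage / config.voltage_opt) / config.log_voltage_width
    return config.peak_probability * math.exp(-0.5 * (zf * zf + zu * zu))


def _copula_rho(config: BehaviorGenConfig) -> float:
    """Latent Gaussian-copula correlation hitting the target Pearson r.

    For freq = m_F + s_F Z1 and dur = exp(mu + sigma Z2) with
    corr(Z1, Z2) = rho, the Pearson correlation is exactly
    rho * sigma * mean_dur / sd_dur, so rho has a closed form.
    """
    sigma2 = math.log1p((config.dur_sd / config.dur_mean) ** 2)
    sigma = math.sqrt(sigma2)
    rho = config.dur_freq_corr * config.dur_sd / (sigma * config.dur_mean)
    if not (-1.0 < rho < 1.0):
        raise ValueError(
            "dur_freq_corr is unreachable for these marginals "
            f"(latent correlation {rho:.3f} outside (-1, 1))"
        )
    return rho


def _lognormal_params(config: BehaviorGenConfig) -> tuple[float, float]:
    sigma2 = math.log1p((config.dur_sd / config.dur_mean) ** 2)
    mu = math.log(config.dur_mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_behavior_trials(config: BehaviorGenConfig) -> list[TrialRecord]:
    """Generate the full stimulation-trial table for the configured grid.

    Each (F, U) cell gets ``trials_per_cell`` Bernoulli trials at the
    success-surface probability; initiated trials draw a correlated
    (flapping frequency, flapping duration) response pair; non-initiated
    trials carry null responses.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    rho = _copula_rho(config)
    mu, sigma = _lognormal_params(config)
    records: list[TrialRecord] = []
    for f_stim in config.grid_frequencies:
        for u_stim in config.grid_voltages:
            p = success_probability(config, f_stim, u_stim)
            m = config.trials_per_cell
            initiated = rng.random(m) < p
            k = int(initiated.sum())
            z1 = rng.standard_normal(k)
            z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(k)
            freqs = config.freq_mean + config.freq_sd * z1
            durs = np.exp(mu + sigma * z2)
            j = 0
            for hit in initiated:
                flap_freq = flap_dur = None
                if hit:
                    flap_freq = float(freqs[j])
                    flap_dur = float(durs[j])
                    j += 1
                records.append(TrialRecord(
                    stim_freq=f_stim, stim_voltage=u_stim,
                    duty_ratio=config.duty_ratio, polarity=config.polarity,
                    stim_duration=config.stim_duration_s,
                    initiated=bool(hit), flap_freq=flap_freq, flap_dur=flap_dur,
                ))
    return records


def generate_initiated_responses(
    config: BehaviorGenConfig, n: int
) -> list[TrialRecord]:
    """Draw initiated trials at the surface optimum until ``n`` are collected.

    Convenience for response-statistics studies: runs single-cell batches at
    (freq_opt, voltage_opt) and returns the first ``n`` initiated records.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p_opt = success_probability(config, config.freq_opt, config.voltage_opt)
    if p_opt <= 0:
        raise ValueError("peak probability is zero; no trial can initiate")
    collected: list[TrialRecord] = []
    batch = max(int(1.2 * n / p_opt), 64)
    seed_offset = 0
    while len(collected) < n:
        cfg = BehaviorGenConfig(**{
            **asdict(config),
            "grid_frequencies": (config.freq_opt,),
            "grid_voltages": (config.voltage_opt,),
            "trials_per_cell": batch,
            "seed": config.seed + seed_offset,
        })
        collected.extend(t for t in generate_behavior_trials(cfg) if t.initiated)
        seed_offset += 1
    return collected[:n]
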