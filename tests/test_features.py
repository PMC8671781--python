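"""Band power, peak detection, state rule, transition frequency."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beelfp import (
    PSDEstimate,
    SpectralFeatures,
    band_power,
    classify_state,
    detect_flapband_peak,
    find_transition_frequency,
    fluctuation_score,
)
from beelfp.spectral import AveragePSD


def make_psd(power, fmax=500.0):
    power = np.asarray(power, dtype=float)
    freqs = np.linspace(0.0, fmax, power.size)
    return PSDEstimate(frequencies=freqs, power=power, nfft=2 * (power.size - 1))


def gaussian_bump(freqs, center, width, height=1.0):
    return height * np.exp(-0.5 * ((freqs - center) / width) ** 2)


class TestBandPower:
    def test_flat_spectrum_rectangle(self):
        psd = make_psd(np.full(101, 2.0), fmax=100.0)
        assert band_power(psd, 0.0, 15.0) == pytest.approx(30.0)

    def test_zero_spectrum(self):
        psd = make_psd(np.zeros(64), fmax=100.0)
        assert band_power(psd, 0.0, 50.0) == 0.0

    def test_gaussian_bump_inside_band_captures_its_integral(self):
        freqs = np.linspace(0.0, 100.0, 2001)
        power = gaussian_bump(freqs, 25.0, 1.0)
        psd = PSDEstimate(frequencies=freqs, power=power, nfft=4000)
        total = np.trapezoid(power, freqs)
        assert band_power(psd, 20.0, 30.0) >= 0.99 * total

    def test_band_outside_grid_rejected(self):
        psd = make_psd(np.ones(11), fmax=10.0)
        with pytest.raises(ValueError):
            band_power(psd, 5.0, 20.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=1, max_value=99))
    def test_additive_over_interior_split(self, split_idx):
        rng = np.random.default_rng(0)
        psd = make_psd(rng.uniform(0.0, 5.0, 101), fmax=100.0)
        b = float(psd.frequencies[split_idx])
        lo, hi = 0.0, 100.0
        if not (lo < b < hi):
            return
        whole = band_power(psd, lo, hi)
        parts = band_power(psd, lo, b) + band_power(psd, b, hi)
        assert whole == pytest.approx(parts, rel=1e-9)


class TestDetectFlapbandPeak:
    def test_single_bump_located(self):
        freqs = np.linspace(0.0, 100.0, 401)
        psd = PSDEstimate(freqs, gaussian_bump(freqs, 25.0, 2.0) + 0.01, nfft=800)
        freq, prom = detect_flapband_peak(psd)
        assert freq == pytest.approx(25.0, abs=freqs[1] - freqs[0])
        assert prom >= 1.0

    def test_monotone_spectrum_has_no_peak(self):
        freqs = np.linspace(0.0, 100.0, 201)
        psd = PSDEstimate(freqs, 1.0 / (freqs + 1.0), nfft=400)
        assert detect_flapband_peak(psd) is None

    def test_out_of_band_bump_ignored_in_band_bump_found(self):
        freqs = np.linspace(0.0, 100.0, 401)
        power = (gaussian_bump(freqs, 10.0, 1.5, height=5.0)
                 + gaussian_bump(freqs, 25.0, 1.5, height=1.0) + 0.01)
        psd = PSDEstimate(freqs, power, nfft=800)
        freq, _ = detect_flapband_peak(psd)
        assert freq == pytest.approx(25.0, abs=0.5)


class TestClassifyState:
    def _features(self, prom, fluct, low):
        return SpectralFeatures(
            lowband_power=low,
            flapband_peak_freq=None if prom is None else 25.0,
            flapband_peak_prominence=prom,
            fluctuation_score=fluct,
        )

    def test_no_peak_no_fluctuation_is_calm(self):
        f = self._features(None, 0, 10.0)
        assert classify_state(f, calm_reference_lowband=10.0) == "calm"

    def test_peak_with_elevated_lowband_is_flapping(self):
        f = self._features(2.0, 1, 20.0)
        assert classify_state(f, calm_reference_lowband=10.0) == "flapping"

    def test_peak_alone_without_second_cue_is_calm(self):
        f = self._features(2.0, 1, 10.0)
        assert classify_state(f, calm_reference_lowband=10.0) == "calm"

    def test_peak_with_fluctuation_needs_no_reference(self):
        f = self._features(2.0, 5, 10.0)
        call = classify_state(
            f, thresholds={"lowband_ratio_min": None},
        )
        assert call == "flapping"

    def test_missing_reference_is_configuration_error(self):
        f = self._features(2.0, 1, 10.0)
        with pytest.raises(ValueError, match="calm_reference_lowband"):
            classify_state(f)

    def test_deterministic(self):
        f = self._features(1.8, 2, 15.0)
        calls = {classify_state(f, calm_reference_lowband=10.0) for _ in range(5)}
        assert len(calls) == 1


class TestFluctuationScore:
    def test_counts_bumps_below_50hz_only(self):
        freqs = np.linspace(0.0, 100.0, 1001)
        power = (0.01 + gaussian_bump(freqs, 10, 1) + gaussian_bump(freqs, 25, 1)
                 + gaussian_bump(freqs, 40, 1) + gaussian_bump(freqs, 80, 1))
        psd = PSDEstimate(freqs, power, nfft=2000)
        assert fluctuation_score(psd) == 3


class TestTransitionFrequency:
    def _avg(self, freqs, power):
        return AveragePSD(frequencies=freqs, mean_power=power,
                          error=np.zeros_like(power), n_samples=1)

    def test_constant_offset_has_no_crossing(self):
        f = np.linspace(0.0, 100.0, 101)
        calm = self._avg(f, np.ones_like(f))
        flap = self._avg(f, np.ones_like(f) + 1.0)
        assert find_transition_frequency(flap, calm) is None

    def test_linear_difference_crosses_at_root(self):
        f = np.linspace(0.0, 100.0, 101)
        calm = self._avg(f, np.full_like(f, 50.0))
        flap = self._avg(f, 50.0 + (30.0 - f))
        assert find_transition_frequency(flap, calm) == pytest.approx(30.0)

    def test_lowest_crossing_wins(self):
        f = np.linspace(0.0, 100.0, 1001)
        diff = np.sin(2 * np.pi * f / 40.0)  # + to - at 20, 60, ...
        calm = self._avg(f, np.full_like(f, 10.0))
        flap = self._avg(f, 10.0 + diff)
        assert find_transition_frequency(flap, calm) == pytest.approx(20.0, abs=0.1)
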