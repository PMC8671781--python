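"""Burg AR fitting and AR spectrum evaluation.

The lattice recursion is checked against a brute-force loop oracle (no
shared code) and against the independent Burg implementation in
statsmodels; the spectrum against closed-form AR shapes and pole placement.
"""
import numpy as np
import pytest
from statsmodels.regression.linear_model import burg as sm_burg

from beelfp import ARModel, SignalTrace, ar_psd, average_psd, burg_ar, estimate_psd

FS = 1000.0


def brute_force_burg(x, order):
    """Direct-loop Burg lattice: reference oracle, intentionally naive."""
    x = [float(v) for v in x]
    n = len(x)
    f = list(x)
    b = list(x)
    a = [1.0] + [0.0] * order
    e = sum(v * v for v in x) / n
    for m in range(1, order + 1):
        num = 0.0
        den = 0.0
        for t in range(m, n):
            num += f[t] * b[t - 1]
            den += f[t] * f[t] + b[t - 1] * b[t - 1]
        k = 0.0 if den == 0.0 else -2.0 * num / den
        a_new = list(a)
        for i in range(1, m + 1):
            a_new[i] = a[i] + k * a[m - i]
        a = a_new
        f_new = [f[t] + k * b[t - 1] for t in range(m, n)]
        b_new = [b[t - 1] + k * f[t] for t in range(m, n)]
        for idx, t in enumerate(range(m, n)):
            f[t] = f_new[idx]
            b[t] = b_new[idx]
        e *= 1.0 - k * k
    return a[1:], e


def simulate_ar(phi, n, seed, burn=200):
    rng = np.random.default_rng(seed)
    p = len(phi)
    x = np.zeros(n + burn)
    e = rng.standard_normal(n + burn)
    for t in range(p, n + burn):
        x[t] = sum(phi[k] * x[t - 1 - k] for k in range(p)) + e[t]
    out = x[burn:]
    return out - out.mean()


class TestBurgAr:
    def test_two_sample_closed_form(self):
        model = burg_ar(np.array([1.0, 1.0]), order=1, sampling_rate=FS)
        assert model.reflection_coefficients[0] == pytest.approx(-1.0)
        assert model.coefficients[0] == pytest.approx(-1.0)
        assert model.noise_variance == pytest.approx(0.0)

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    @pytest.mark.parametrize("n", [8, 16, 64])
    def test_matches_brute_force_oracle(self, order, n):
        rng = np.random.default_rng(order * 100 + n)
        x = rng.standard_normal(n)
        x -= x.mean()
        model = burg_ar(x, order=order, sampling_rate=FS)
        a_ref, e_ref = brute_force_burg(x, order)
        np.testing.assert_allclose(model.coefficients, a_ref, atol=1e-10)
        assert model.noise_variance == pytest.approx(e_ref, abs=1e-10)

    def test_matches_statsmodels_convention_flipped(self):
        x = simulate_ar([0.6, -0.3], 2048, seed=5)
        model = burg_ar(x, order=2, sampling_rate=FS)
        phi_sm, _ = sm_burg(x, order=2, demean=False)
        np.testing.assert_allclose(model.coefficients, -phi_sm, atol=1e-8)

    def test_recovers_ar1_coefficient(self):
        x = simulate_ar([0.5], 4096, seed=0)
        model = burg_ar(x, order=1, sampling_rate=FS)
        assert -0.55 <= model.coefficients[0] <= -0.45

    def test_white_noise_coefficients_vanish(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(4096)
        x -= x.mean()
        model = burg_ar(x, order=15, sampling_rate=FS)
        assert np.max(np.abs(model.coefficients)) < 0.1

    def test_reflection_coefficients_bounded(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(512)
            x -= x.mean()
            model = burg_ar(x, order=15, sampling_rate=FS)
            assert np.all(np.abs(model.reflection_coefficients) <= 1.0)

    def test_order_must_be_below_length(self):
        with pytest.raises(ValueError):
            burg_ar(np.zeros(10) + [1, -1, 1, -1, 1, -1, 1, -1, 1, -1],
                    order=10, sampling_rate=FS)

    def test_zero_signal_gives_zero_model(self):
        model = burg_ar(np.zeros(64), order=4, sampling_rate=FS)
        np.testing.assert_allclose(model.coefficients, 0.0)
        assert model.noise_variance == 0.0

    def test_nonzero_mean_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="DC-free"):
            burg_ar(rng.standard_normal(256) + 5.0, order=2, sampling_rate=FS)


class TestArPsd:
    def test_order_zero_like_flat_spectrum(self):
        model = ARModel(order=1, coefficients=np.array([0.0]),
                        noise_variance=2.0, sampling_rate=FS)
        psd = ar_psd(model, nfft=256)
        # one-sided: interior bins doubled, edges not
        assert psd.power[1:-1] == pytest.approx(2 * 2.0 / FS)
        assert psd.power[0] == pytest.approx(2.0 / FS)
        assert psd.frequencies[0] == 0.0
        assert psd.frequencies[-1] == pytest.approx(FS / 2)
        assert len(psd.frequencies) == 129

    def test_ar1_spectrum_density_decreases_from_zero(self):
        model = ARModel(order=1, coefficients=np.array([-0.9]),
                        noise_variance=1.0, sampling_rate=FS)
        psd = ar_psd(model, nfft=1024)
        # undo the one-sided doubling at the edges: the underlying density
        # of a positively correlated AR(1) is maximal at DC and monotone
        density = psd.power.copy()
        density[1:-1] /= 2.0
        assert np.argmax(density) == 0
        assert np.all(np.diff(density) < 0)

    def test_ar2_conjugate_poles_peak_at_pole_frequency(self):
        f0, r = 25.0, 0.98
        a1 = -2 * r * np.cos(2 * np.pi * f0 / FS)
        a2 = r * r
        model = ARModel(order=2, coefficients=np.array([a1, a2]),
                        noise_variance=1.0, sampling_rate=FS)
        psd = ar_psd(model, nfft=1024)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert abs(peak - f0) <= FS / 1024

    def test_unstable_model_refused(self):
        model = ARModel(order=1, coefficients=np.array([-1.2]),
                        noise_variance=1.0, sampling_rate=FS,
                        reflection_coefficients=np.array([-1.2]))
        with pytest.raises(ValueError, match="unstable"):
            ar_psd(model, nfft=256)

    def test_spectrum_integral_approximates_variance(self):
        x = simulate_ar([0.5, -0.2], 4096, seed=11)
        psd = estimate_psd(SignalTrace(x, FS), order=4, nfft=1024)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(np.var(x), rel=0.2)


class TestAveragePsd:
    def _psd(self, power):
        x = simulate_ar([0.3], 256, seed=1)
        base = estimate_psd(SignalTrace(x, FS), order=2, nfft=64)
        base.power = np.full_like(base.power, float(power))
        return base

    def test_identical_copies_have_zero_error(self):
        est = self._psd(1.0)
        avg = average_psd([est, est, est], error_kind="SD")
        np.testing.assert_allclose(avg.mean_power, est.power)
        np.testing.assert_allclose(avg.error, 0.0)

    def test_two_point_mean_and_sd(self):
        avg = average_psd([self._psd(1.0), self._psd(3.0)], error_kind="SD")
        assert avg.mean_power[0] == pytest.approx(2.0)
        assert avg.error[0] == pytest.approx(np.sqrt(2.0))

    def test_sem_scales_sd(self):
        ests = [self._psd(1.0), self._psd(3.0)]
        sd = average_psd(ests, error_kind="SD")
        sem = average_psd(ests, error_kind="SEM")
        np.testing.assert_allclose(sem.error, sd.error / np.sqrt(2))

    def test_mismatched_grids_rejected(self):
        a = self._psd(1.0)
        x = simulate_ar([0.3], 256, seed=2)
        b = estimate_psd(SignalTrace(x, FS / 2), order=2, nfft=64)
        with pytest.raises(ValueError):
            average_psd([a, b])
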