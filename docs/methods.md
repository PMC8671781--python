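# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want spelled
out. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Signal model and preprocessing

A recording is modeled as a single uniformly sampled voltage channel
(µV) from one optic lobe. Raw traces carry a DC offset from the
electrode interface and a slow baseline wander concentrated near 0.7 Hz
(respiration/body movement of the tethered animal) that must be removed
before spectral analysis, because both corrupt the low-frequency end of
the spectrum where the state contrast lives.

**DC removal** zeroes the zero-frequency Fourier coefficient (forward
FFT, zero bin 0, inverse FFT), which is numerically identical to mean
subtraction; the operation is idempotent and leaves length and rate
unchanged.

**Baseline correction** uses empirical mode decomposition. Sifting:
find local extrema; interpolate upper and lower cubic-spline envelopes;
subtract the envelope mean; repeat until the normalized squared
successive difference `Σ(h_prev − h)² / Σh_prev²` falls below
`stop_threshold` (default 0.2) *and* the candidate satisfies the IMF
definition (|#extrema − #zero-crossings| ≤ 1), with a 200-sift cap.
Accepted IMFs are subtracted and extraction continues until the residue
is monotone/has fewer than three extrema or `max_imfs` (default 12) is
reached. Completeness (`input = Σ IMFs + residue`) is exact by
construction.

Envelope boundary handling matters more than the literature usually
admits: two extrema are mirrored past each end, and an endpoint that
overshoots its nearest extremum is promoted to an extremum before
mirroring. Without that promotion, the spline swings wildly at the ends
and dumps wander energy into mid-frequency IMFs.

Each IMF's mean frequency is the zero-crossing estimate
`(#crossings / 2) / ((n − 1)/fs)`. The corrected trace is the sum of
IMFs at or above `cutoff_hz`; sub-cutoff IMFs and the residue are
discarded (the trend is the limit case of the wander). **The default
cutoff is 3.5 Hz, not ~2× the wander frequency.** The reason is mode
mixing: a wander-carrying IMF retains small riding oscillations whose
extra zero crossings inflate its frequency estimate to as much as
~4× the true 0.7 Hz, so a cutoff near 1.5 Hz retains large wander
fractions in a substantial minority of traces. At 3.5 Hz the sub-1 Hz
band power of default-amplitude synthetic traces is reduced by ≥ 90%
in 80/80 trace-state combinations tested while ≥ 90% of 20–30 Hz band
power is always retained. The trade-off — genuine 1.5–3.5 Hz content is
also discarded — is acceptable because no feature downstream depends on
that sliver, and the cutoff remains a flag for data where it does.

## Burg AR spectral estimation

The AR(p) model `x_t + Σ a_k x_{t−k} = e_t` is fit by the Burg lattice:
forward/backward prediction errors are initialized to the signal and at
stage m the reflection coefficient
`k_m = −2 Σ f(t) b(t−1) / Σ (f(t)² + b(t−1)²)` drives a Levinson update
of the coefficients; the noise variance starts at the signal power and
shrinks by `(1 − k_m²)` per stage. |k_m| ≤ 1 holds by construction, so
the spectrum is always evaluable. Defaults: order 15, nfft 1024, grid
`f_j = j·fs/nfft` for `j = 0..nfft/2`, one-sided doubling at interior
bins, units µV²/Hz. No windowing or segment averaging — the model is
fit to whole traces, which is the point of a parametric estimator on
short records. No automatic order selection; the order is a parameter.

One consequence of the one-sided doubling convention: the DC bin is not
doubled, so for a monotone-decreasing density the *plotted* maximum sits
at bin 1. Tests on density shapes undo the doubling first.

The spectrum integral only approximates the sample variance (within
~20% for AR-generated test signals): finite-sample AR spectra are not
Parseval-exact, and the tolerance is deliberately loose.

## Features and the state rule

- `band_power`: trapezoidal integral with interpolated band edges, so
  power is additive across adjacent bands.
- `detect_flapband_peak`: highest strict local maximum inside 20–30 Hz;
  prominence = peak power / median in-band power; plateaus break toward
  the lower frequency.
- `fluctuation_score`: count of strict local maxima of log-power below
  50 Hz.
- `classify_state`: flapping iff (in-band peak with prominence ≥ 1.5)
  AND (fluctuation_score ≥ 3 OR low-band 0–15 Hz power ≥ 1.3× a calm
  reference). The rule is a declared operationalization of three
  qualitative cues (in-band peak, curve fluctuation, low-band
  elevation); all thresholds are configuration. In practice, at
  order 15 / nfft 1024 the AR spectrum is smooth enough that the
  fluctuation count rarely exceeds 1, so the second clause is carried
  by the low-band ratio; the fluctuation clause is kept because it is
  the natural cue for higher-order or nonparametric spectra.
- `find_transition_frequency`: lowest frequency where the
  flap-minus-calm average PSD changes sign from positive to negative,
  linearly interpolated between bracketing bins.

## Synthetic data: what it emulates, and what it does not

**LFP generator.** A trace is DC offset (20 µV) + wander (100 µV
sinusoid at 0.7 Hz with random phase, plus a random walk scaled to 15%
of the wander amplitude, so the wander is not a single deterministic
tone) + Gaussian background shaped as 1/f^β (β = 1, gain clamped below
0.1 Hz, scaled to 20 µV RMS). The flapping state adds a 60 µV
oscillation whose instantaneous frequency is frequency-modulated inside
20–30 Hz, multiplies background power below 15 Hz by 4.0, and
multiplies it above 15 Hz by 0.6. The boost/attenuation pair models a
redistribution of power toward low frequencies during flight and is
what gives the two average spectra a crossing (the transition
frequency). Defaults: 1000 Hz sampling (Nyquist-safe for the flap band,
resolves the wander), 10 s duration (≥ 7 wander cycles).

The flapping-state amplitudes were chosen once, jointly with the
paper-fixed analysis settings (AR order 15, nfft 1024), so that the
generated regime actually exhibits the structure the analysis is meant
to detect: with a substantially weaker oscillation or boost, an AR(15)
fit over a 1/f background spends its seven pole pairs on the
low-frequency roll-off and resolves neither the in-band peak nor the
low-band elevation — no threshold tuning can recover a feature the
estimator cannot represent. At the chosen values the in-band peak, the
low-band elevation, and the crossing are all present with margin
(measured by the acceptance tests, not assumed).

Not emulated: stimulation artifacts, mains interference, nonstationary
state transitions within a trace, inter-animal variability of
background shape, electrode drift other than the random walk. Passing
tests therefore demonstrate the pipeline's correctness on signals with
the assumed structure, not robustness to every artifact of real
recordings.

**Behavioral generator.** Each cell of the stimulation grid (defaults:
F ∈ {3, 20, 40, 60, 80, 100} Hz × U ∈ {3..8} V) receives
`trials_per_cell` Bernoulli trials with success probability
`p(F, U) = 0.85 · exp(−ln²(F/60)/(2·1.0²)) · exp(−ln²(U/7)/(2·0.4²))` —
a separable log-Gaussian surface, unimodal with mode (60 Hz, 7 V),
peak probability 0.85 so the best observed cell rate clears an 80%
criterion with margin. Log-space widths (1.0 in F, 0.4 in U) were
chosen so the surface falls to near zero at the grid edges in F and
roughly halves at the voltage extremes, matching a rise-and-fall
screening profile.

Initiated trials draw a response pair: flapping frequency
`~ N(120.657, 20.225²)` Hz; flapping duration lognormal matched by
moments to mean 448.143 / SD 411.659 ms (an SD comparable to the mean
rules out a symmetric Gaussian without truncation artifacts, and
duration is strictly positive); the two are coupled by a Gaussian
copula. The latent correlation has a closed form — for
`freq = m + s·Z₁`, `dur = exp(µ + σ·Z₂)`, `corr(Z₁, Z₂) = ρ`, the
Pearson correlation is exactly `ρ·σ·mean_dur/sd_dur` — giving
ρ ≈ −0.4105 for a target r of −0.35. Note the target r and SDs imply a
duration–frequency covariance near −2914 ms·Hz; the generator is
calibrated to r and the marginal SDs, and `summarize_flight` reports
whatever covariance the sample realizes.

## Problem sizes and numerical choices

- Acceptance-style tests use 100 random traces of 1000 samples for EMD
  structure, 100 seeds of n = 4096 for AR(4) recovery (test process
  `φ = (2.7607, −3.8106, 2.6535, −0.9238)`, two sharp conjugate pole
  pairs), 100 traces per state at full 10 s length for the spectral
  contrast and classification checks, and 10,000 initiated trials for
  the behavioral statistics.
- Brute-force oracles (direct-loop Burg lattice, hand-rolled Pearson)
  live in the test suite and share no code with the implementation;
  statsmodels' Burg routine provides an additional independent
  cross-check (its coefficient sign convention is the negation of
  ours).
- Degenerate inputs: a zero signal yields a zero AR model; a trace with
  fewer than three extrema decomposes to an empty IMF list with the
  trace as residue; a cutoff above every component returns a zero trace
  with a logged warning; fewer than two complete response pairs is an
  error for the flight summary.
- Seeds: every generator consumes a `numpy` `SeedSequence` spawned from
  the config seed plus a stream tag, so flapping/calm traces from one
  seed are distinct but individually reproducible, and identical
  configs are bit-identical.

## Known limitations

- Plain EMD only: no ensemble/complete-ensemble variants, so mode
  mixing under intermittent noise is handled by the conservative
  cutoff rather than by the decomposition itself.
- The zero-crossing frequency estimate is biased upward for impure
  IMFs; it is retained because it is simple, deterministic, and the
  basis of the documented cutoff choice.
- The state rule is threshold-based, not learned; its accuracy figure
  is specific to the generator's regime.
- Success-rate inference is purely descriptive (no interval estimates
  or tests on the surface).
- The first screening stage of the stimulation grid (coarser F/U
  ranges) is not reproduced; only the refined grid is modeled.
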