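"""Evoked-CAP extraction, exponential fits and derived statistics."""

import math

import numpy as np
import pytest

import xenovocal as xv
from xenovocal.potentiation import PotentiationSeries


def _series(stim_freq, amps, lats=None, failures=None):
    n = len(amps)
    amps = np.asarray(amps, dtype=float)
    lats = np.asarray(lats, dtype=float) if lats is not None else np.full(n, 6.5)
    failures = np.asarray(failures, dtype=bool) if failures is not None \
        else np.zeros(n, dtype=bool)
    amps = np.where(failures, np.nan, amps)
    lats = np.where(failures, np.nan, lats)
    return PotentiationSeries(stim_freq=stim_freq,
                              pulse_order=np.arange(1, n + 1),
                              amplitude=amps, latency_ms=lats,
                              failures=failures)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_noiseless_plateau_latency_recovered_to_one_sample(clean_stim):
    series = xv.extract_stim_responses(clean_stim)[0]
    assert xv.plateau_latency(series, after_pulse=15) == pytest.approx(6.5, abs=0.1)


def test_extraction_matches_generator_ground_truth(clean_stim):
    series = xv.extract_stim_responses(clean_stim)[0]
    truth_amp = np.array(clean_stim.meta["pulse_amplitude"], dtype=float)
    assert not series.failures.any()
    assert np.allclose(series.amplitude, truth_amp, rtol=0.02)
    truth_lat = np.array(clean_stim.meta["pulse_latency_ms"], dtype=float)
    assert np.allclose(series.latency_ms, truth_lat, atol=0.11)


def test_sub_threshold_frequency_gives_all_failures():
    rec = xv.synth_stim_response(xv.SynapseParams(), stim_freq=5.0,
                                 n_pulses=12, seed=1)
    for series in xv.extract_stim_responses(rec):
        assert series.failures.all()


def test_extraction_requires_stim_times(petersii_fictive):
    with pytest.raises(xv.ValidationError):
        xv.extract_stim_responses(petersii_fictive)


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def test_noiseless_tau_recovered_to_relative_1e3(clean_stim):
    series = xv.extract_stim_responses(clean_stim)[0]
    fit = xv.fit_potentiation(series, "rising")
    assert abs(fit.tau - 6.90) <= 1e-3 * 6.90
    # latency is quantized to the 0.1 ms sample grid, which bounds tau
    # recovery at roughly +-0.12 pulses for the preset decay
    lat_fit = xv.fit_potentiation(series, "falling")
    assert abs(lat_fit.tau - 3.64) <= 0.12


def test_noisy_tau_is_unbiased_within_ten_percent():
    rng = np.random.default_rng(9)
    t = np.arange(1, 31)
    true_tau, A, C = 6.90, 300.0, 20.0
    taus = []
    for _ in range(100):
        y = C + A * (1 - np.exp(-t / true_tau)) + rng.normal(0, 0.05 * A, t.size)
        fit = xv.fit_potentiation(_series(30.0, y), "rising")
        taus.append(fit.tau)
    assert abs(np.mean(taus) - true_tau) <= 0.10 * true_tau


def test_constant_series_is_degenerate():
    with pytest.warns(xv.DegenerateFitWarning):
        fit = xv.fit_potentiation(_series(30.0, np.full(12, 5.0)), "rising")
    assert fit.degenerate and fit.A == pytest.approx(0.0, abs=1e-9)


def test_wrong_direction_is_rejected_by_sign_check():
    t = np.arange(1, 21)
    falling = 6.5 + 5.0 * np.exp(-t / 3.0)
    with pytest.raises(xv.FitFailureError):
        xv.fit_potentiation(_series(30.0, falling), "rising")
    rising = 20.0 + 300.0 * (1 - np.exp(-t / 6.9))
    with pytest.raises(xv.FitFailureError):
        xv.fit_potentiation(_series(30.0, rising, lats=rising), "falling")


def test_fit_preconditions():
    with pytest.raises(xv.InsufficientEventsError):
        xv.fit_potentiation(_series(30.0, np.arange(5.0)), "rising")
    y = np.arange(1, 13, dtype=float)
    with pytest.raises(xv.ValidationError):
        xv.fit_potentiation(_series(8.0, y), "rising")


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tau, expected", [(6.90, 21), (3.64, 11), (2.69, 8)])
def test_pulses_to_95_percent(tau, expected):
    assert xv.pulses_to_fraction(tau, 0.95) == expected


def test_pulses_to_fraction_monotonic():
    taus = [1.0, 2.69, 3.64, 6.90, 20.0]
    vals = [xv.pulses_to_fraction(t) for t in taus]
    assert vals == sorted(vals)
    fracs = [0.5, 0.8, 0.95, 0.99]
    vals_f = [xv.pulses_to_fraction(6.9, f) for f in fracs]
    assert vals_f == sorted(vals_f)


def test_tau_frequency_regression_cases():
    flat = [(10.0, 6.9), (20.0, 6.9), (30.0, 6.9), (50.0, 6.9)]
    res = xv.tau_frequency_regression(flat)
    assert res.F == 0.0 and res.slope == 0.0

    linear = [(10.0, 5.0), (20.0, 6.0), (30.0, 7.0), (40.0, 8.0)]
    res2 = xv.tau_frequency_regression(linear)
    assert res2.p <= 1e-6

    with pytest.raises(xv.InsufficientEventsError):
        xv.tau_frequency_regression([(10.0, 5.0), (20.0, 6.0)])


def test_tau_regression_type_one_error_rate_under_the_null():
    rng = np.random.default_rng(12)
    freqs = np.repeat([15.0, 20.0, 30.0, 40.0, 60.0], 5)
    ok = 0
    for _ in range(200):
        taus = rng.normal(6.9, 1.0, size=freqs.size)
        res = xv.tau_frequency_regression(list(zip(freqs, taus)))
        ok += res.p > 0.05
    assert ok >= 180  # frequency-independent taus rarely look significant


def test_regression_F_invariant_to_frequency_rescaling():
    rng = np.random.default_rng(4)
    pairs = [(f, 6.9 + rng.normal(0, 1)) for f in (10, 20, 30, 40, 50)]
    res_hz = xv.tau_frequency_regression(pairs)
    res_khz = xv.tau_frequency_regression([(f / 1000.0 + 2.0, t) for f, t in pairs])
    assert res_hz.F == pytest.approx(res_khz.F, rel=1e-9)


def test_min_effective_frequency_threshold_and_sentinel():
    trials = []
    for f in (1.0, 5.0, 10.0, 20.0):
        rec = xv.synth_stim_response(xv.SynapseParams(min_freq=10.0),
                                     stim_freq=f, n_pulses=20, seed=3)
        trials.extend(xv.extract_stim_responses(rec))
    assert xv.min_effective_frequency(trials) == 10.0

    dead = [_series(f, np.full(20, np.nan), lats=np.full(20, np.nan),
                    failures=np.ones(20, dtype=bool)) for f in (5.0, 20.0)]
    assert math.isinf(xv.min_effective_frequency(dead))


def test_plateau_latency_needs_late_successes():
    fails = np.zeros(20, dtype=bool)
    fails[15:] = True
    s = _series(30.0, np.ones(20), failures=fails)
    with pytest.raises(xv.InsufficientEventsError):
        xv.plateau_latency(s, after_pulse=15)
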