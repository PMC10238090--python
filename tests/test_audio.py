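"""Click detection, rate statistics and Gaussian rate models."""

import numpy as np
import pytest

import xenovocal as xv
from xenovocal.audio import RateHistogram


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def test_envelope_of_silence_is_zero():
    env = xv.envelope(np.zeros(5000), sample_rate=44100.0)
    assert np.all(env == 0)


def test_envelope_peaks_at_the_click():
    fs = 44100.0
    rec = xv.synth_call_audio("X_amieti", n_calls=1, seed=1, snr=None,
                              clicks_per_call=2)
    env = xv.envelope(rec)
    t_true = rec.meta["click_times"][0]
    # envelope maximum near the first click lies within +-2 ms of it
    sel = slice(0, int((t_true + 0.01) * fs))
    t_peak = np.argmax(env[sel]) / fs
    assert abs(t_peak - t_true) <= 2e-3


def test_envelope_scales_linearly():
    rng = np.random.default_rng(0)
    x = rng.normal(size=4000)
    e1 = xv.envelope(x, sample_rate=44100.0)
    e2 = xv.envelope(2.0 * x, sample_rate=44100.0)
    assert np.allclose(e2, 2.0 * e1)


def test_envelope_requires_audio_channel(petersii_fictive):
    with pytest.raises(xv.MissingChannelError):
        xv.envelope(petersii_fictive)


# ---------------------------------------------------------------------------
# click picking
# ---------------------------------------------------------------------------

def test_detected_click_count_matches_ground_truth(amieti_audio):
    env = xv.envelope(amieti_audio)
    train = xv.detect_clicks(env, amieti_audio.sample_rate)
    assert len(train) == len(amieti_audio.meta["click_times"])


def test_pure_noise_rarely_triggers_the_detector():
    fs = 44100.0
    empty = 0
    for seed in range(100):
        x = np.random.default_rng(seed).normal(0, 0.1, size=int(0.2 * fs))
        train = xv.detect_clicks(xv.envelope(x, fs), fs)
        empty += len(train) == 0
    assert empty >= 99


def test_refractory_merges_nearby_clicks():
    fs = 10000.0
    env = np.zeros(200)
    env[50] = 1.0
    env[70] = 0.8  # 2 ms later
    train = xv.detect_clicks(env, fs, refractory_ms=4.0)
    assert len(train) == 1


def test_empty_signal_yields_empty_train():
    train = xv.detect_clicks(np.zeros(0), 44100.0)
    assert len(train) == 0


# ---------------------------------------------------------------------------
# rates, histogram, classification
# ---------------------------------------------------------------------------

def test_instantaneous_rates_are_reciprocal_intervals():
    train = xv.EventTrain(times=[0.0, 0.01, 0.02], amplitudes=[1, 1, 1])
    assert np.allclose(xv.instantaneous_rates(train), [100.0, 100.0])
    pair = xv.EventTrain(times=[0.0, 1 / 143.0], amplitudes=[1, 1])
    assert np.allclose(xv.instantaneous_rates(pair), [143.0])
    with pytest.raises(xv.InsufficientEventsError):
        xv.instantaneous_rates(xv.EventTrain(times=[0.1], amplitudes=[1]))


def test_rate_histogram_bins_and_normalization():
    h = xv.rate_histogram(np.full(7, 100.4))
    assert h.bin_edges[0] == 100 and h.bin_edges[-1] == 101
    assert np.allclose(h.heights, [1.0])

    h2 = xv.rate_histogram(np.array([30.2, 60.7]))
    nz = h2.heights[h2.heights > 0]
    assert np.allclose(nz, [0.5, 0.5])
    assert np.all(np.diff(h2.bin_edges) == 1.0)

    rng = np.random.default_rng(1)
    rates = rng.uniform(20, 80, size=333)
    h3 = xv.rate_histogram(rates)
    assert np.isclose(h3.heights.sum() * rates.size, rates.size)
    with pytest.raises(xv.InsufficientEventsError):
        xv.rate_histogram(np.empty(0))


@pytest.mark.parametrize("rate, label", [
    (60.0, "fast"), (30.0, "slow"), (42.0, "unlabeled"),
    (50.0, "unlabeled"), (35.0, "unlabeled"),
])
def test_rate_classification_cutoffs(rate, label):
    assert xv.classify_rate(rate) == label


def test_call_segmentation_counts_and_bounds(amieti_audio):
    env = xv.envelope(amieti_audio)
    train = xv.detect_clicks(env, amieti_audio.sample_rate)
    segs = xv.call_segmentation(train, gap_s=0.5)
    assert len(segs) == 2
    assert sum(s.click_count for s in segs) == len(train)
    single = xv.EventTrain(times=[1.0], amplitudes=[1.0])
    segs1 = xv.call_segmentation(single)
    assert len(segs1) == 1 and segs1[0].click_count == 1


# ---------------------------------------------------------------------------
# Gaussian rate models
# ---------------------------------------------------------------------------

def _hist_from_draws(rng, means, sd, n_per):
    rates = np.concatenate([rng.normal(m, sd, size=n_per) for m in means])
    return xv.rate_histogram(rates)


def test_unimodal_fit_is_self_consistent_on_an_exact_curve():
    edges = np.arange(120.0, 171.0)
    centers = edges[:-1] + 0.5
    mu, sigma, amp = 143.0, 5.0, 0.08
    heights = amp * np.exp(-((centers - mu) ** 2) / (2 * sigma ** 2))
    fit = xv.fit_rate_model(RateHistogram(edges, heights), "unimodal")
    assert fit.sse <= 1e-10
    assert abs(fit.mus[0] - mu) <= 1e-6


def test_unimodal_fit_recovers_fast_clicker_mean():
    rng = np.random.default_rng(42)
    hist = _hist_from_draws(rng, [143.0], 5.0, 2000)
    fit = xv.fit_rate_model(hist, "unimodal")
    assert abs(fit.mus[0] - 143.0) <= 1.0


def test_bimodal_fit_recovers_both_biphasic_modes():
    rng = np.random.default_rng(7)
    hist = _hist_from_draws(rng, [69.9, 31.3], 3.0, 1000)
    fit = xv.fit_rate_model(hist, "bimodal")
    lo, hi = fit.mus
    assert lo < hi  # components sorted by mu ascending
    assert abs(lo - 31.3) <= 1.0
    assert abs(hi - 69.9) <= 1.0
    for _mu, sigma, amp in fit.components:
        assert sigma > 0 and amp > 0


def test_bimodal_fit_on_unimodal_data_is_flagged_not_spurious():
    rng = np.random.default_rng(3)
    hist = _hist_from_draws(rng, [143.0], 5.0, 2000)
    import warnings
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        fit = xv.fit_rate_model(hist, "bimodal")
    warned = any(issubclass(w.category, xv.DegenerateFitWarning) for w in rec)
    mu1, mu2 = fit.mus
    amps = sorted(c[2] for c in fit.components)
    near_identical = abs(mu2 - mu1) < 5.0
    minor = amps[0] <= 0.1 * amps[1]
    assert warned or near_identical or minor


def test_bimodal_fit_requires_enough_nonzero_bins():
    h = xv.rate_histogram(np.full(50, 100.2))
    with pytest.raises(xv.ValidationError):
        xv.fit_rate_model(h, "bimodal")
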