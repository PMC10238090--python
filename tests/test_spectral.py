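"""Normalized LFP power spectra and the twice-noise activity rule."""

import numpy as np
import pytest

import xenovocal as xv


def test_pure_sinusoid_peaks_at_its_frequency():
    fs = 10000.0
    t = np.arange(int(fs)) / fs
    res = xv.psd(np.sin(2 * np.pi * 60.0 * t), fs)
    assert res.peak_freq == pytest.approx(60.0, abs=1.0)
    assert res.power.max() == pytest.approx(1.0, abs=1e-12)


def test_zero_and_short_segments_are_rejected():
    with pytest.raises(xv.ValidationError):
        xv.psd(np.zeros(4096), 10000.0)
    with pytest.raises(xv.ValidationError):
        xv.psd(np.ones(100), 10000.0)


def test_normalized_psd_is_scale_invariant():
    x = np.random.default_rng(0).normal(size=4096)
    a = xv.psd(x, 10000.0)
    b = xv.psd(123.4 * x, 10000.0)
    assert np.allclose(a.power, b.power)
    assert a.peak_freq == b.peak_freq


def test_mean_psd_idempotent_and_bounded():
    x = np.random.default_rng(1).normal(size=4096)
    p = xv.psd(x, 10000.0)
    m = xv.mean_psd([p, p, p])
    assert np.allclose(m.power, p.power)
    y = np.random.default_rng(2).normal(size=4096)
    m2 = xv.mean_psd([p, xv.psd(y, 10000.0)])
    assert m2.power.max() <= 1.0 + 1e-12


def test_mixed_segment_lengths_raise():
    x = np.random.default_rng(3).normal(size=8192)
    with pytest.raises(xv.ResolutionMismatchError):
        xv.mean_psd([xv.psd(x, 10000.0), xv.psd(x[:4096], 10000.0)])


@pytest.mark.parametrize("profile", ["X_amieti", "X_cliivi", "X_laevis_male"])
def test_locked_lfp_peak_tracks_the_cap_rate(profile):
    # the spectral peak of the phase-locked LFP falls within mean +- std of
    # the measured CAP rates of the same recording
    rec = xv.synth_fictive_recording(profile, seed=55, clicks_per_phase=80)
    fs = rec.sample_rate
    train = xv.detect_caps(rec.channel("left_nerve"), fs)
    calls = xv.segment_fictive_calls(train)
    phase = next(p for c in calls for p in c.phases if p.label == "fast")
    seg = rec.channel("pbn_lfp")[int(phase.onset * fs):int(phase.offset * fs)]
    rates = 1.0 / np.diff(train.times[(train.times >= phase.onset)
                                      & (train.times <= phase.offset)])
    res = xv.psd(seg, fs)
    assert rates.mean() - rates.std() <= res.peak_freq <= rates.mean() + rates.std()


def test_silent_lfp_mean_spectrum_has_no_fast_band_peak():
    powers = []
    for seed in range(12):
        rec = xv.synth_fictive_recording("X_amieti", seed=100 + seed,
                                         lfp_mode="silent")
        seg = rec.channel("pbn_lfp")[:8192]
        powers.append(xv.psd(seg, rec.sample_rate))
    m = xv.mean_psd(powers)
    band = (m.freqs >= 50) & (m.freqs <= 160)
    assert m.power[band].max() <= 3.0 * np.median(m.power[band])


def test_twice_noise_rule_on_generator_modes(petersii_fictive):
    rec = petersii_fictive
    fs = rec.sample_rate
    b0, b1 = rec.meta["baseline_span"]
    baseline = rec.channel("pbn_lfp")[int(b0 * fs):int(b1 * fs)]
    lfp = rec.channel("pbn_lfp")
    for ph in rec.meta["phases"]:
        seg = lfp[int(ph["onset"] * fs):int(ph["offset"] * fs)]
        active, ratio = xv.pbn_active(seg, baseline)
        if ph["label"] == "fast":
            assert active and ratio >= 2.0
        else:
            assert not active and ratio < 2.0

    weak = xv.synth_fictive_recording("X_petersii", seed=77, lfp_mode="weak")
    wl = weak.channel("pbn_lfp")
    for ph in weak.meta["phases"]:
        seg = wl[int(ph["onset"] * fs):int(ph["offset"] * fs)]
        active, _ = xv.pbn_active(seg, wl[:int(0.4 * fs)])
        assert not active


def test_equal_amplitude_is_inactive_with_ratio_one():
    x = np.random.default_rng(5).normal(size=4000)
    active, ratio = xv.pbn_active(x, x)
    assert not active and ratio == pytest.approx(1.0)
    with pytest.raises(xv.ValidationError):
        xv.pbn_active(np.empty(0), x)
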