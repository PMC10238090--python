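"""Generator contracts: ground truth, determinism, and boundary cases."""

import numpy as np
import pytest

import xenovocal as xv
from xenovocal.profiles import SpeciesProfile


def test_zero_variance_profile_gives_exact_intervals():
    profile = SpeciesProfile(name="flat", call_type="monophasic_fast",
                             fast_rate_mean=100.0, fast_rate_sd=0.0,
                             clicks_per_phase_mean=20)
    rec = xv.synth_call_audio(profile, n_calls=1, seed=0)
    iv = np.diff(rec.meta["click_times"])
    assert np.allclose(iv, 0.010, atol=1e-12)


def test_requested_calls_appear_as_silence_separated_groups():
    rec = xv.synth_call_audio("X_cliivi", n_calls=2, seed=3)
    times = np.asarray(rec.meta["click_times"])
    n_groups = 1 + int(np.sum(np.diff(times) >= 0.5))
    assert n_groups == 2
    assert len(rec.meta["call_spans"]) == 2


def test_nonpositive_call_count_rejected():
    with pytest.raises(xv.ValidationError):
        xv.synth_call_audio("X_amieti", n_calls=0, seed=0)


def test_same_seed_reproduces_bit_identical_recordings():
    a = xv.synth_fictive_recording("X_petersii", seed=7)
    b = xv.synth_fictive_recording("X_petersii", seed=7)
    c = xv.synth_fictive_recording("X_petersii", seed=8)
    for role in a.channels:
        assert np.array_equal(a.channels[role], b.channels[role])
    assert not np.array_equal(a.channel("left_nerve"), c.channel("left_nerve"))


def test_zero_lag_zero_jitter_gives_sample_identical_nerves():
    rec = xv.synth_fictive_recording("X_laevis_male", lag_fast_ms=0.0,
                                     lag_slow_ms=0.0, lag_jitter_ms=0.0,
                                     seed=5, snr=None)
    assert np.array_equal(rec.channel("left_nerve"), rec.channel("right_nerve"))


def test_lag_outside_search_window_rejected():
    with pytest.raises(xv.ValidationError):
        xv.synth_fictive_recording("X_laevis_male", lag_fast_ms=12.0, seed=0)
    # the female release preset allows the wider +-50 ms window
    rec = xv.synth_fictive_recording("X_laevis_female_release",
                                     lag_slow_ms=20.0, seed=0)
    assert rec.meta["lag_slow_ms"] == 20.0


def test_sub_threshold_stimulus_frequency_evokes_no_caps():
    params = xv.SynapseParams(min_freq=10.0)
    rec = xv.synth_stim_response(params, stim_freq=5.0, n_pulses=20, seed=1)
    assert all(rec.meta["pulse_failed"])
    assert all(v is None for v in rec.meta["pulse_amplitude"])


def test_failure_prob_one_flags_every_pulse():
    params = xv.SynapseParams(failure_prob=1.0)
    rec = xv.synth_stim_response(params, stim_freq=30.0, n_pulses=15, seed=2)
    assert all(rec.meta["pulse_failed"])
    series = xv.extract_stim_responses(rec)[0]
    assert series.failure_fraction == 1.0


def test_amplitude_saturates_by_pulse_21_for_preset_tau():
    params = xv.SYNAPSE_PRESETS["X_laevis_male"]  # tau_amp = 6.90, a = 1
    rec = xv.synth_stim_response(params, stim_freq=30.0, n_pulses=30, seed=0,
                                 trace_snr=None)
    amps = rec.meta["pulse_amplitude"]
    assert amps[20] >= 0.95 * (params.C_amp + params.A_amp)


def test_stim_times_match_requested_train():
    rec = xv.synth_stim_response(xv.SynapseParams(), stim_freq=25.0,
                                 n_pulses=10, seed=0)
    assert rec.stim_times.size == 10
    assert np.allclose(np.diff(rec.stim_times), 0.04)
    with pytest.raises(xv.ValidationError):
        xv.synth_stim_response(xv.SynapseParams(), stim_freq=25.0,
                               n_pulses=0, seed=0)


def test_ground_truth_times_strictly_increasing(petersii_fictive):
    for role in ("left_nerve", "right_nerve"):
        t = np.asarray(petersii_fictive.meta["cap_times"][role])
        assert np.all(np.diff(t) > 0)
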