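"""Phenomenological generators for call audio and ex-vivo recordings.

Three generators mirror the study's recording types:

* :func:`synth_call_audio` — hydrophone-style call audio: each click is a
  short damped sinusoid at the species' carrier frequency, with inter-click
  intervals drawn as 1/rate, rate ~ Normal(mean, sd) truncated at 1 Hz.
* :func:`synth_fictive_recording` — paired laryngeal-nerve traces carrying
  identical CAP sequences (the right channel optionally delayed during fast
  and/or slow phases, modeling a unilateral transection) plus a
  parabrachial-nucleus LFP channel that is phase-locked to fast CAPs.
* :func:`synth_stim_response` — stimulus-train-evoked CAP series whose
  amplitude potentiates and latency shortens exponentially with pulse order.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
seeds reproduce bit-identical recordings. Ground truth (event times, phase
spans, imposed lags, per-pulse amplitude/latency/failure) is stored in
``Recording.meta``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.stats import norm

from .errors import ValidationError
from .profiles import SpeciesProfile, SynapseParams, make_species_profile
from .recording import (
    ROLE_AUDIO,
    ROLE_LEFT_NERVE,
    ROLE_PBN_LFP,
    ROLE_RIGHT_NERVE,
    Recording,
)

# 99.5th percentile of the standard normal: |noise| stays below this times
# sigma 99% of the time; used to express LFP amplitudes in "times noise".
_NOISE_99 = float(norm.ppf(0.995))

#: LFP oscillation amplitude relative to the 99th-percentile noise amplitude.
#: The measured segment amplitude includes the noise floor on top of the
#: oscillation, so the weak ratio sits well below 2 to keep weak mode under
#: the twice-noise rule everywhere.
LFP_FAST_RATIO = 5.0  # phasic_fast_only mode, comfortably above the 2x rule
LFP_WEAK_RATIO = 1.2  # weak mode, below the 2x rule everywhere

LFP_MODES = ("phasic_fast_only", "silent", "weak")

_LEAD_IN_S = 0.5  # call-free baseline before the first call
_CALL_GAP_S = 1.0  # silence between calls (> default 0.5 s segmentation gap)
_TAIL_S = 0.3


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def click_waveform(sample_rate: float, carrier_hz: float, dur_ms: float = 4.0,
                   decay_ms: float = 1.0) -> np.ndarray:
    """Damped sinusoid used as the audio click atom (unit peak)."""
    t = np.arange(int(round(dur_ms * 1e-3 * sample_rate))) / sample_rate
    w = np.exp(-t / (decay_ms * 1e-3)) * np.sin(2 * np.pi * carrier_hz * t)
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def cap_waveform(sample_rate: float, width_ms: float = 2.5) -> np.ndarray:
    """Biphasic CAP atom: difference of Gaussians, positive peak first.

    Total width ``width_ms``; unit positive peak. The array's ``argmax`` is
    the nominal event time used when stamping the waveform.
    """
    half = width_ms / 2.0
    t = np.arange(-half * 1e-3, half * 1e-3, 1.0 / sample_rate)
    s = width_ms / 6.0 * 1e-3  # Gaussian width
    d = width_ms / 5.0 * 1e-3  # lobe separation
    # the trailing negative lobe is smaller than the leading positive peak,
    # so the |x| maximum identifies the positive peak unambiguously
    w = np.exp(-((t + d) ** 2) / (2 * s * s)) \
        - 0.6 * np.exp(-((t - d) ** 2) / (2 * s * s))
    return w / np.max(w)


def _stamp(signal_arr: np.ndarray, wave: np.ndarray, peak_sample: int,
           scale: float = 1.0) -> None:
    """Add ``scale * wave`` so that the wave's argmax lands on peak_sample."""
    m = int(np.argmax(wave))
    start = peak_sample - m
    stop = start + wave.size
    lo = max(start, 0)
    hi = min(stop, signal_arr.size)
    if hi <= lo:
        return
    signal_arr[lo:hi] += scale * wave[lo - start:hi - start]


def _truncated_rates(rng: np.random.Generator, mean: float, sd: float,
                     n: int, floor: float = 1.0) -> np.ndarray:
    """Normal rate draws truncated (by redraw) at ``floor`` Hz."""
    if sd == 0:
        return np.full(n, float(mean))
    rates = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = rates < floor
        if not bad.any():
            break
        rates[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(rates, floor, None)


def _highpassed_noise(rng: np.random.Generator, n: int, sample_rate: float,
                      sd: float, corner_hz: float = 10.0) -> np.ndarray:
    """Gaussian background noise, high-passed at the channel's low corner."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    pad = int(round(0.2 * sample_rate))  # discard filter edge transients
    x = rng.normal(0.0, sd, size=n + 2 * pad)
    sos = sps.butter(2, corner_hz, btype="highpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x)[pad:pad + n]


def _resolve_profile(profile) -> SpeciesProfile:
    return make_species_profile(profile) if isinstance(profile, str) else profile


def _phase_click_times(rng, profile, clicks_per_phase, t0):
    """Per-call click times and phase spans starting at ``t0``.

    Returns (times, labels, phase_spans) where phase_spans is a list of
    (label, onset, offset) with offset = last click of the phase.
    """
    times, labels, spans = [], [], []
    t = t0
    for label in profile.phase_order:
        mean, sd = profile.phase_rate(label)
        n = clicks_per_phase[label] if isinstance(clicks_per_phase, dict) \
            else int(clicks_per_phase)
        if n < 2:
            raise ValidationError("each phase needs at least 2 clicks")
        if times:  # contiguous phases: one interval at the new phase's rate
            t = times[-1] + 1.0 / _truncated_rates(rng, mean, sd, 1)[0]
        rates = _truncated_rates(rng, mean, sd, n - 1)
        phase_times = t + np.concatenate([[0.0], np.cumsum(1.0 / rates)])
        times.extend(phase_times.tolist())
        labels.extend([label] * n)
        spans.append((label, float(phase_times[0]), float(phase_times[-1])))
    return np.asarray(times), labels, spans


# ---------------------------------------------------------------------------
# call audio
# ---------------------------------------------------------------------------

def synth_call_audio(profile, n_calls: int, seed: int,
                     sample_rate: float = 44100.0, snr: float = 10.0,
                     clicks_per_call=None) -> Recording:
    """Synthesize single-channel call audio with known click times.

    Parameters
    ----------
    profile : SpeciesProfile or str
        Species preset (or its name).
    n_calls : int
        Number of calls, separated by 1 s of silence.
    seed : int
        Generator seed; identical seeds give bit-identical audio.
    snr : float
        Click peak amplitude over background-noise standard deviation.
    clicks_per_call : int, dict or None
        Clicks per phase; defaults to the profile's ``clicks_per_phase_mean``.
    """
    profile = _resolve_profile(profile)
    if n_calls < 1:
        raise ValidationError("n_calls must be at least 1")
    rng = np.random.default_rng(seed)
    per_phase = clicks_per_call if clicks_per_call is not None \
        else profile.clicks_per_phase_mean

    click_times, call_spans = [], []
    t = _LEAD_IN_S
    for _ in range(n_calls):
        times, _labels, _spans = _phase_click_times(rng, profile, per_phase, t)
        click_times.extend(times.tolist())
        call_spans.append((float(times[0]), float(times[-1])))
        t = times[-1] + _CALL_GAP_S

    n = int(round((click_times[-1] + _TAIL_S) * sample_rate))
    x = rng.normal(0.0, 1.0 / snr, size=n) if snr and np.isfinite(snr) else np.zeros(n)
    wave = click_waveform(sample_rate, profile.click_carrier_freq)
    for ct in click_times:
        _stamp(x, wave, int(round(ct * sample_rate)))

    meta = {
        "seed": int(seed),
        "profile": profile.name,
        "scenario": "call_audio",
        "click_times": [float(v) for v in click_times],
        "call_spans": [[a, b] for a, b in call_spans],
    }
    return Recording(sample_rate=sample_rate, channels={ROLE_AUDIO: x}, meta=meta)


# ---------------------------------------------------------------------------
# paired-nerve + LFP fictive recording
# ---------------------------------------------------------------------------

def synth_fictive_recording(profile, n_calls: int = 1, lag_fast_ms: float = 0.0,
                            lag_slow_ms: float = 0.0, lag_jitter_ms: float = 0.0,
                            lfp_mode: str = "phasic_fast_only", seed: int = 0,
                            sample_rate: float = 10000.0, snr: float = 10.0,
                            clicks_per_phase=None) -> Recording:
    """Paired laryngeal-nerve + PBN LFP recording with controllable lag.

    The left and right nerves carry identical CAP sequences except that the
    right channel's CAP times are shifted by ``lag_fast_ms`` during fast
    phases and ``lag_slow_ms`` during slow phases (plus per-CAP Gaussian
    jitter of sd ``lag_jitter_ms``), modeling a unilateral transection
    between the parabrachial nucleus and the nucleus ambiguus. The LFP
    channel is, in ``phasic_fast_only`` mode, an oscillation with one cycle
    per fast CAP at about five times the noise amplitude (and noise only
    during slow phases); ``weak`` mode phase-locks to every CAP at below
    twice the noise amplitude; ``silent`` mode is noise only.
    """
    profile = _resolve_profile(profile)
    if n_calls < 1:
        raise ValidationError("n_calls must be at least 1")
    if lfp_mode not in LFP_MODES:
        raise ValidationError(f"lfp_mode must be one of {LFP_MODES}")
    if lag_jitter_ms < 0:
        raise ValidationError("lag_jitter_ms must be nonnegative")
    bound = 50.0 if profile.name == "X_laevis_female_release" else 10.0
    if abs(lag_fast_ms) > bound or abs(lag_slow_ms) > bound:
        raise ValidationError(
            f"imposed lag exceeds the ±{bound:g} ms search window for "
            f"{profile.name} and would be undetectable downstream"
        )
    rng = np.random.default_rng(seed)
    per_phase = clicks_per_phase if clicks_per_phase is not None \
        else profile.clicks_per_phase_mean
    lag_by_label = {"fast": lag_fast_ms * 1e-3, "slow": lag_slow_ms * 1e-3}

    left_times, labels, phase_spans, call_spans = [], [], [], []
    t = _LEAD_IN_S
    for _ in range(n_calls):
        times, lab, spans = _phase_click_times(rng, profile, per_phase, t)
        left_times.extend(times.tolist())
        labels.extend(lab)
        phase_spans.extend(spans)
        call_spans.append((float(times[0]), float(times[-1])))
        t = times[-1] + _CALL_GAP_S
    left_times = np.asarray(left_times)
    jitter = rng.normal(0.0, lag_jitter_ms * 1e-3, size=left_times.size) \
        if lag_jitter_ms > 0 else np.zeros(left_times.size)
    right_times = left_times + np.array([lag_by_label[l] for l in labels]) + jitter

    n = int(round((max(left_times[-1], right_times[-1]) + _TAIL_S) * sample_rate))
    noise_sd = 1.0 / snr if snr and np.isfinite(snr) else 0.0
    wave = cap_waveform(sample_rate)
    chans = {}
    for role, times_arr in ((ROLE_LEFT_NERVE, left_times),
                            (ROLE_RIGHT_NERVE, right_times)):
        x = _highpassed_noise(rng, n, sample_rate, noise_sd, corner_hz=10.0)
        for ct in times_arr:
            _stamp(x, wave, int(round(ct * sample_rate)))
        chans[role] = x

    # LFP: baseline noise plus one sine cycle per CAP in the driven phases.
    lfp_sd = 0.05
    lfp = rng.normal(0.0, lfp_sd, size=n)
    if lfp_mode != "silent":
        ratio = LFP_FAST_RATIO if lfp_mode == "phasic_fast_only" else LFP_WEAK_RATIO
        amp = ratio * _NOISE_99 * lfp_sd
        driven = {"fast"} if lfp_mode == "phasic_fast_only" else {"fast", "slow"}
        tax = np.arange(n) / sample_rate
        for i, (ct, lab) in enumerate(zip(left_times, labels)):
            if lab not in driven:
                continue
            nxt = left_times[i + 1] if (i + 1 < left_times.size
                                        and labels[i + 1] == lab) else None
            dt = (nxt - ct) if nxt is not None else (
                ct - left_times[i - 1] if i > 0 and labels[i - 1] == lab else 0.02)
            i0 = int(round(ct * sample_rate))
            i1 = min(int(round((ct + dt) * sample_rate)), n)
            if i1 > i0:
                lfp[i0:i1] += amp * np.sin(2 * np.pi * (tax[i0:i1] - ct) / dt)
    chans[ROLE_PBN_LFP] = lfp

    meta = {
        "seed": int(seed),
        "profile": profile.name,
        "scenario": f"fictive:{lfp_mode}",
        "lag_fast_ms": float(lag_fast_ms),
        "lag_slow_ms": float(lag_slow_ms),
        "lag_jitter_ms": float(lag_jitter_ms),
        "cap_times": {
            ROLE_LEFT_NERVE: [float(v) for v in left_times],
            ROLE_RIGHT_NERVE: [float(v) for v in right_times],
        },
        "cap_labels": list(labels),
        "phases": [{"label": l, "onset": a, "offset": b}
                   for l, a, b in phase_spans],
        "call_spans": [[a, b] for a, b in call_spans],
        "baseline_span": [0.0, _LEAD_IN_S - 0.05],
    }
    return Recording(sample_rate=sample_rate, channels=chans, meta=meta)


# ---------------------------------------------------------------------------
# stimulus-evoked potentiation series
# ---------------------------------------------------------------------------

def synth_stim_response(params: SynapseParams, stim_freq: float, n_pulses: int,
                        seed: int, sample_rate: float = 10000.0,
                        trace_snr: float | None = 10.0) -> Recording:
    """Stimulus-train recording with potentiating evoked CAPs.

    ``stim_times`` contains ``n_pulses`` events at interval ``1/stim_freq``.
    Below ``params.min_freq`` no CAPs are placed (every pulse is flagged as a
    failure in the ground truth). ``trace_snr`` sets the background-noise
    level relative to the amplitude asymptote; ``None`` gives clean traces.
    """
    if n_pulses < 1:
        raise ValidationError("n_pulses must be at least 1")
    if stim_freq <= 0:
        raise ValidationError("stim_freq must be positive")
    rng = np.random.default_rng(seed)
    t0 = 0.1
    stim_times = t0 + np.arange(n_pulses) / stim_freq
    order = np.arange(1, n_pulses + 1)

    if stim_freq < params.min_freq:
        failed = np.ones(n_pulses, dtype=bool)
        amps = np.full(n_pulses, np.nan)
        lats = np.full(n_pulses, np.nan)
    else:
        failed = rng.random(n_pulses) < params.failure_prob
        amp_mean = params.C_amp + params.A_amp * (
            1.0 - np.exp(-order / params.tau_amp)) ** params.a_amp
        lat_mean = params.C_lat + (params.L0 - params.C_lat) * (
            np.exp(-order / params.tau_lat)) ** params.a_lat
        amps = amp_mean + (rng.normal(0.0, params.noise_sd_amp, n_pulses)
                           if params.noise_sd_amp > 0 else 0.0)
        lats = lat_mean + (rng.normal(0.0, params.noise_sd_lat, n_pulses)
                           if params.noise_sd_lat > 0 else 0.0)
        amps = np.clip(amps, 1e-6, None)
        lats = np.clip(lats, 0.5, None)
        amps[failed] = np.nan
        lats[failed] = np.nan

    n = int(round((stim_times[-1] + 0.05) * sample_rate))
    wave = cap_waveform(sample_rate)
    full_amp = params.C_amp + params.A_amp
    noise_sd = full_amp / trace_snr if trace_snr else 0.0
    chans = {}
    for role in (ROLE_LEFT_NERVE, ROLE_RIGHT_NERVE):
        x = _highpassed_noise(rng, n, sample_rate, noise_sd, corner_hz=10.0)
        for st, a, l, f in zip(stim_times, amps, lats, failed):
            if f:
                continue
            _stamp(x, wave, int(round((st + l * 1e-3) * sample_rate)), scale=a)
        chans[role] = x

    meta = {
        "seed": int(seed),
        "scenario": "stim_response",
        "stim_freq": float(stim_freq),
        "synapse_params": {k: float(v) for k, v in vars(params).items()},
        "pulse_amplitude": [None if np.isnan(a) else float(a) for a in amps],
        "pulse_latency_ms": [None if np.isnan(l) else float(l) for l in lats],
        "pulse_failed": [bool(f) for f in failed],
    }
    return Recording(sample_rate=sample_rate, channels=chans,
                     stim_times=stim_times, meta=meta)


def synth_locked_lfp(rate_hz: float, duration_s: float = 1.0,
                     sample_rate: float = 10000.0, snr: float = 4.0,
                     seed: int = 0) -> np.ndarray:
    """1-channel LFP segment phase-locked to a regular CAP train.

    One oscillation cycle per CAP at ``rate_hz``, amplitude ``snr`` times the
    99th-percentile noise amplitude — the configuration used to check that
    the LFP spectral peak falls at the CAP repetition rate.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValidationError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    sd = 0.05
    x = rng.normal(0.0, sd, size=n)
    amp = snr * _NOISE_99 * sd
    t = np.arange(n) / sample_rate
    x += amp * np.sin(2 * np.pi * rate_hz * t)
    return x
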