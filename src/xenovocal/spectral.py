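"""Power spectral density of parabrachial-nucleus LFP segments.

Each segment gets a single Hann-windowed periodogram normalized to its own
maximum (no within-segment averaging, which would change the spectral
resolution); mean spectra are averages of already-normalized PSDs from
segments of identical length. PBN activity during a call is classified by
the twice-noise rule: the call-segment amplitude (99th percentile of |x|)
must reach twice the amplitude of a call-free baseline segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ResolutionMismatchError, ValidationError

DEFAULT_BAND = (5.0, 200.0)
MIN_SEGMENT = 256


@dataclass
class PSDResult:
    """Normalized power spectral density of one (or a mean of) segment(s)."""

    freqs: np.ndarray  # Hz
    power: np.ndarray  # normalized, max 1 for a single segment
    segment_len: int  # samples; sets the spectral resolution fs/N
    peak_freq: float  # Hz, frequency of the maximum within ``band``
    band: tuple = DEFAULT_BAND


def _band_peak(freqs: np.ndarray, power: np.ndarray, band) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError("analysis band contains no frequency bins")
    fsel = freqs[sel]
    return float(fsel[int(np.argmax(power[sel]))])


def psd(segment: np.ndarray, sample_rate: float, band=DEFAULT_BAND,
        window: str = "hann") -> PSDResult:
    """Hann-windowed periodogram normalized to its maximum.

    ``peak_freq`` is the frequency of the maximum normalized power within
    ``band`` (default 5–200 Hz, covering all species' CAP rates). The
    normalization makes the result invariant to positive rescaling of the
    input; an all-zero segment is rejected rather than divided by zero.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < MIN_SEGMENT:
        raise ValidationError(
            f"segment too short: {segment.size} < {MIN_SEGMENT} samples")
    if not np.any(segment):
        raise ValidationError("all-zero segment has no normalizable spectrum")
    freqs, power = sps.periodogram(segment, fs=sample_rate, window=window)
    power = power / power.max()
    return PSDResult(freqs=freqs, power=power, segment_len=segment.size,
                     peak_freq=_band_peak(freqs, power, band), band=tuple(band))


def mean_psd(psds: list) -> PSDResult:
    """Element-wise mean of normalized spectra at one spectral resolution.

    All inputs must share the same segment length (hence frequency grid);
    the mean is *not* re-normalized, so its maximum is at most 1.
    """
    if not psds:
        raise ValidationError("no spectra to average")
    n0 = psds[0].segment_len
    if any(p.segment_len != n0 for p in psds):
        raise ResolutionMismatchError(
            "spectra have different segment lengths; averaging would mix "
            f"spectral resolutions (got {sorted({p.segment_len for p in psds})})")
    power = np.mean([p.power for p in psds], axis=0)
    band = psds[0].band
    freqs = psds[0].freqs
    return PSDResult(freqs=freqs, power=power, segment_len=n0,
                     peak_freq=_band_peak(freqs, power, band), band=band)


def pbn_active(lfp_call_segment: np.ndarray,
               lfp_baseline_segment: np.ndarray) -> tuple:
    """Twice-noise activity rule for the PBN LFP.

    Amplitude is the 99th percentile of |x| per segment (robust to isolated
    spikes); the nucleus counts as active when the call-segment amplitude is
    at least twice the baseline amplitude. Returns ``(active, ratio)``.
    """
    call = np.asarray(lfp_call_segment, dtype=float)
    base = np.asarray(lfp_baseline_segment, dtype=float)
    if call.size == 0 or base.size == 0:
        raise ValidationError("call and baseline segments must be nonempty")
    a_call = float(np.percentile(np.abs(call), 99))
    a_base = float(np.percentile(np.abs(base), 99))
    if a_base == 0:
        raise ValidationError("baseline segment has zero amplitude")
    ratio = a_call / a_base
    return ratio >= 2.0, ratio
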