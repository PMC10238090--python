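"""Stimulus-evoked CAP series: potentiation curves and derived statistics.

Repetitive parabrachial stimulation above ~10 Hz evokes laryngeal-nerve
CAPs whose amplitude potentiates and whose latency (stimulus onset to CAP
peak) shortens with pulse order. Both follow a saturating exponential in
pulse order t: rising series are fitted as ``C + A*(1 - exp(-t/tau))**a``
and falling series as ``C + A*exp(-t/tau)`` (the same family under
reparameterization), with tau in units of stimulus pulses. Derived
quantities: the pulse count to reach a fraction of the asymptote
(``round(-tau*ln(1-f))``), the plateau latency after a given pulse, the
tau-vs-stimulus-frequency regression, and the minimum stimulus frequency
that reliably evokes CAPs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .caps import detection_traces
from .errors import (
    DegenerateFitWarning,
    FitFailureError,
    InsufficientEventsError,
    ValidationError,
)
from .recording import Recording

RISING = "rising"
FALLING = "falling"


@dataclass
class PotentiationSeries:
    """Per-pulse evoked-CAP amplitude and latency for one nerve channel.

    ``amplitude`` (response units) and ``latency_ms`` are NaN exactly where
    ``failures`` is True.
    """

    stim_freq: float  # Hz
    pulse_order: np.ndarray  # 1..n
    amplitude: np.ndarray
    latency_ms: np.ndarray
    failures: np.ndarray
    channel_role: str = "left_nerve"

    def __post_init__(self):
        self.pulse_order = np.asarray(self.pulse_order, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.latency_ms = np.asarray(self.latency_ms, dtype=float)
        self.failures = np.asarray(self.failures, dtype=bool)
        n = self.pulse_order.size
        if not (self.amplitude.size == self.latency_ms.size
                == self.failures.size == n):
            raise ValidationError("per-pulse arrays must have equal length")
        if n > 1 and np.any(np.diff(self.pulse_order) <= 0):
            raise ValidationError("pulse_order must be strictly increasing")
        present = ~self.failures
        if np.any(np.isnan(self.amplitude[present])) or \
                np.any(~np.isnan(self.amplitude[~present])):
            raise ValidationError("amplitude present iff pulse not failed")

    @property
    def n_pulses(self) -> int:
        return self.pulse_order.size

    @property
    def failure_fraction(self) -> float:
        return float(self.failures.mean())


@dataclass
class ExponentialFit:
    """Saturating-exponential fit to a potentiation series."""

    A: float
    tau: float  # pulses
    a: float
    C: float
    r: float  # correlation of fit vs data
    sse: float
    direction: str
    degenerate: bool = False


def extract_stim_responses(rec: Recording, window_ms: float = 15.0,
                           threshold_k: float = 6.0,
                           smooth_ms: float = 1.0) -> list:
    """Measure per-pulse CAP amplitude and latency on each nerve channel.

    For each stimulus time the window ``(stim, stim + window_ms]`` is
    searched for a suprathreshold CAP (same robust threshold as
    :func:`xenovocal.caps.detect_caps`); amplitude is the peak |x| in the
    window and latency the peak time minus stimulus onset. A window with no
    suprathreshold peak is a failure.
    """
    if rec.stim_times.size == 0:
        raise ValidationError("recording has no stim_times")
    fs = rec.sample_rate
    diffs = np.diff(rec.stim_times)
    stim_freq = float(np.round(1.0 / np.median(diffs), 9)) if diffs.size else np.nan
    win_n = int(round(window_ms * 1e-3 * fs))
    out = []
    for role in rec.nerve_roles():
        x = rec.channel(role)
        a, det, thr = detection_traces(x, fs, threshold_k, smooth_ms)
        n_p = rec.stim_times.size
        amps = np.full(n_p, np.nan)
        lats = np.full(n_p, np.nan)
        failed = np.ones(n_p, dtype=bool)
        for j, st in enumerate(rec.stim_times):
            i0 = int(round(st * fs)) + 1  # half-open (stim, stim + window]
            i1 = min(i0 + win_n, rec.n_samples)
            if i1 <= i0:
                continue
            if det[i0:i1].max() <= thr:
                continue
            p = i0 + int(np.argmax(a[i0:i1]))
            failed[j] = False
            amps[j] = float(a[p])
            lats[j] = (p / fs - st) * 1e3
        out.append(PotentiationSeries(
            stim_freq=stim_freq, pulse_order=np.arange(1, n_p + 1),
            amplitude=amps, latency_ms=lats, failures=failed,
            channel_role=role))
    return out


def _rising(t, A, tau, a, C):
    return C + A * (1.0 - np.exp(-t / tau)) ** a


def _falling(t, A, tau, a, C):
    return C + A * np.exp(-t / tau) ** a


def fit_potentiation(series: PotentiationSeries, direction: str,
                     vary_a: bool = False, exclude_first: bool = False,
                     variable: str | None = None) -> ExponentialFit:
    """Fit the saturating-exponential model to a potentiation series.

    ``direction="rising"`` fits the amplitude series with
    ``C + A*(1-exp(-t/tau))**a``; ``direction="falling"`` fits the latency
    series with ``C + A*exp(-t/tau)``. The exponent ``a`` is fixed to 1
    unless ``vary_a`` is set, in which case the multistart grid covers
    a in {0.5, 1, 2}. ``exclude_first`` drops pulse 1 (whose response is
    often atypical). Requires at least 8 non-failure pulses and a stimulus
    frequency above 10 Hz, the regime where the evoked series is reliable.
    """
    if direction not in (RISING, FALLING):
        raise ValidationError("direction must be 'rising' or 'falling'")
    if variable is None:
        variable = "amplitude" if direction == RISING else "latency"
    y_all = series.amplitude if variable == "amplitude" else series.latency_ms
    keep = ~series.failures
    if exclude_first:
        keep = keep & (series.pulse_order != 1)
    t = series.pulse_order[keep].astype(float)
    y = y_all[keep]
    if t.size < 8:
        raise InsufficientEventsError(
            f"need at least 8 non-failure pulses, have {t.size}")
    if not np.isnan(series.stim_freq) and series.stim_freq <= 10.0:
        raise ValidationError(
            "potentiation fits are defined for stimulus frequencies above 10 Hz")

    span = float(np.ptp(y))
    if span == 0:
        warnings.warn("constant series: amplitude term degenerates to zero",
                      DegenerateFitWarning, stacklevel=2)
        return ExponentialFit(A=0.0, tau=1.0, a=1.0, C=float(y[0]), r=0.0,
                              sse=0.0, direction=direction, degenerate=True)
    trend = float(np.corrcoef(t, y)[0, 1])
    if direction == RISING and trend < -0.5:
        raise FitFailureError("series is falling; a rising fit would need A < 0")
    if direction == FALLING and trend > 0.5:
        raise FitFailureError("series is rising; a falling fit would need A < 0")

    model = _rising if direction == RISING else _falling
    n = float(t[-1])
    tau_starts = [1.0, n / 6.0, n / 3.0, n]
    a_starts = [0.5, 1.0, 2.0] if vary_a else [1.0]
    c0 = float(y.min())
    best = None
    last_err = None
    for tau0 in tau_starts:
        for a0 in a_starts:
            p0 = [span, tau0, a0, c0]
            lo = [1e-9, 1e-6, a0 if not vary_a else 0.05, -np.inf]
            hi = [np.inf, 100.0 * n, a0 + 1e-12 if not vary_a else 10.0, np.inf]
            try:
                popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lo, hi),
                                    maxfev=20000)
            except (RuntimeError, ValueError) as err:
                last_err = err
                continue
            sse = float(np.sum((y - model(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise FitFailureError(f"exponential fit failed from every start "
                              f"(last error: {last_err})")
    sse, popt = best
    yhat = model(t, *popt)
    r = float(np.corrcoef(y, yhat)[0, 1]) if np.std(yhat) > 0 else 0.0
    A, tau, a, C = (float(v) for v in popt)
    degenerate = A < 1e-6 * span
    if degenerate:
        warnings.warn("fitted amplitude term is negligible",
                      DegenerateFitWarning, stacklevel=2)
    return ExponentialFit(A=A, tau=tau, a=a, C=C, r=r, sse=sse,
                          direction=direction, degenerate=degenerate)


def pulses_to_fraction(tau: float, fraction: float = 0.95) -> int:
    """Pulse count at which the a=1 saturation term reaches ``fraction``.

    ``round(-tau * ln(1 - fraction))``, rounded to the nearest integer.
    """
    if tau <= 0:
        raise ValidationError("tau must be positive")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    return int(math.floor(-tau * math.log1p(-fraction) + 0.5))


class TauRegression(NamedTuple):
    F: float
    p: float
    slope: float


def tau_frequency_regression(taus) -> TauRegression:
    """OLS regression of tau on stimulus frequency with an F-test of slope=0.

    ``taus`` is a sequence of (stim_freq_hz, tau_pulses) pairs spanning at
    least 3 distinct frequencies; the F statistic has (1, n-2) degrees of
    freedom and is invariant to affine rescaling of the frequency axis.
    """
    pairs = [(float(f), float(tv)) for f, tv in taus]
    freqs = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.unique(freqs).size < 3:
        raise InsufficientEventsError(
            "regression needs at least 3 distinct stimulus frequencies")
    if np.ptp(y) == 0:
        return TauRegression(F=0.0, p=1.0, slope=0.0)
    res = linregress(freqs, y)
    if res.stderr == 0:  # perfect linear relation, zero residual
        if res.slope == 0:
            return TauRegression(F=0.0, p=1.0, slope=0.0)
        return TauRegression(F=float("inf"), p=0.0, slope=float(res.slope))
    F = float((res.slope / res.stderr) ** 2)
    return TauRegression(F=F, p=float(res.pvalue), slope=float(res.slope))


def min_effective_frequency(trials, after_pulse: int = 5,
                            success_threshold: float = 0.5) -> float:
    """Lowest stimulus frequency that reliably evokes CAPs.

    For each tested frequency the success rate is the non-failure fraction
    over pulses after ``after_pulse``; the lowest frequency whose rate
    exceeds ``success_threshold`` is returned, or ``math.inf`` when none
    qualifies (the slow-clicker "no response" case).
    """
    if not trials:
        raise ValidationError("no trials given")
    freqs = sorted({float(s.stim_freq) for s in trials})
    if len(freqs) < 2:
        raise ValidationError("trials must span at least 2 frequencies")
    for f in freqs:
        ok = tot = 0
        for s in trials:
            if float(s.stim_freq) != f:
                continue
            late = s.pulse_order > after_pulse
            tot += int(late.sum())
            ok += int((~s.failures[late]).sum())
        if tot and ok / tot > success_threshold:
            return f
    return math.inf


def plateau_latency(series: PotentiationSeries, after_pulse: int = 15) -> float:
    """Mean CAP latency (ms) over non-failure pulses after ``after_pulse``,
    where the latency series has reached its plateau."""
    sel = (series.pulse_order > after_pulse) & ~series.failures
    if not sel.any():
        raise InsufficientEventsError(
            f"no successful pulses after pulse {after_pulse}")
    return float(np.mean(series.latency_ms[sel]))
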