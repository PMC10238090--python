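"""Click detection and click-rate modeling for call audio.

The pipeline mirrors standard bioacoustic practice for click trains: a
rectified, low-passed amplitude envelope; peak picking with a robust
(median + k*MAD) threshold and a refractory interval; instantaneous rates
as 1/inter-click interval; a normalized 1-Hz-binned rate histogram; and a
unimodal or bimodal Gaussian fitted to the histogram by damped least
squares with multistart initialization. Rates above 50 Hz are "fast",
below 35 Hz "slow"; the 35–50 Hz band is deliberately unlabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .errors import (
    DegenerateFitWarning,
    FitFailureError,
    InsufficientEventsError,
    ValidationError,
)
from .events import LABEL_FAST, LABEL_SLOW, LABEL_UNLABELED, EventTrain
from .profiles import FAST_CUTOFF_HZ, SLOW_CUTOFF_HZ
from .recording import ROLE_AUDIO, Recording


# ---------------------------------------------------------------------------
# envelope and click picking
# ---------------------------------------------------------------------------

def envelope(audio, sample_rate: float | None = None,
             cutoff_hz: float = 200.0) -> np.ndarray:
    """Amplitude envelope: full-wave rectification then low-pass smoothing.

    ``audio`` may be a :class:`Recording` (its audio channel is used) or a
    raw vector with ``sample_rate`` given. The result is nonnegative and the
    same length as the input; scaling the input scales the envelope.
    """
    if isinstance(audio, Recording):
        x = audio.channel(ROLE_AUDIO)
        sample_rate = audio.sample_rate
    else:
        x = np.asarray(audio, dtype=float)
        if sample_rate is None:
            raise ValidationError("sample_rate required for a raw vector")
    if x.size == 0:
        return np.zeros(0)
    rect = np.abs(x)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=sample_rate, output="sos")
    env = sps.sosfiltfilt(sos, rect)
    return np.clip(env, 0.0, None)


def _robust_threshold(det: np.ndarray, k: float) -> float:
    """median + k*MAD of the detection trace, with a 10%-of-max fallback
    when MAD degenerates to 0 (noiseless synthetic input)."""
    med = float(np.median(det))
    mad = float(np.median(np.abs(det - med)))
    if mad > 0:
        return med + k * mad
    mx = float(det.max(initial=0.0))
    return med + 0.1 * mx if mx > 0 else np.inf


def detect_clicks(env: np.ndarray, sample_rate: float,
                  threshold_k: float = 8.0,
                  refractory_ms: float = 4.0) -> EventTrain:
    """Pick clicks as envelope local maxima above median + k*MAD.

    Events are separated by at least ``refractory_ms``. An empty or
    all-subthreshold signal yields an empty train (not an error).
    """
    if refractory_ms <= 0:
        raise ValidationError("refractory_ms must be positive")
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        return EventTrain(np.empty(0), np.empty(0), channel_role=ROLE_AUDIO)
    thr = _robust_threshold(env, threshold_k)
    dist = max(1, int(round(refractory_ms * 1e-3 * sample_rate)))
    peaks, _ = sps.find_peaks(env, height=thr, distance=dist)
    return EventTrain(times=peaks / sample_rate, amplitudes=env[peaks],
                      channel_role=ROLE_AUDIO)


# ---------------------------------------------------------------------------
# rates, histogram, classification, segmentation
# ---------------------------------------------------------------------------

def instantaneous_rates(train: EventTrain) -> np.ndarray:
    """Instantaneous event rates, 1/inter-event interval (Hz)."""
    if len(train) < 2:
        raise InsufficientEventsError("need at least 2 events for rates")
    return 1.0 / np.diff(train.times)


def rates_by_call(train: EventTrain, gap_s: float = 0.5) -> np.ndarray:
    """Instantaneous rates pooled per call, excluding inter-call gaps."""
    out = []
    for seg in call_segmentation(train, gap_s):
        if seg.click_count >= 2:
            sub = train.times[(train.times >= seg.onset) & (train.times <= seg.offset)]
            out.append(1.0 / np.diff(sub))
    if not out:
        raise InsufficientEventsError("no call with at least 2 events")
    return np.concatenate(out)


@dataclass
class RateHistogram:
    """Normalized instantaneous-rate histogram at 1 Hz bin width."""

    bin_edges: np.ndarray  # Hz, uniform width 1
    heights: np.ndarray  # normalized frequencies, sum to 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rate_histogram(rates: np.ndarray) -> RateHistogram:
    """1-Hz-binned normalized frequency histogram of instantaneous rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise InsufficientEventsError("no rates to histogram")
    lo = float(np.floor(rates.min()))
    hi = max(float(np.ceil(rates.max())), lo + 1.0)
    edges = np.arange(lo, hi + 1.0)
    counts, _ = np.histogram(rates, bins=edges)
    return RateHistogram(bin_edges=edges, heights=counts / rates.size)


def classify_rate(rate: float) -> str:
    if rate > FAST_CUTOFF_HZ:
        return LABEL_FAST
    if rate < SLOW_CUTOFF_HZ:
        return LABEL_SLOW
    return LABEL_UNLABELED


def classify_rates(rates) -> np.ndarray:
    """Label each rate fast (>50 Hz), slow (<35 Hz) or unlabeled (between)."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    return np.array([classify_rate(r) for r in rates], dtype=object)


@dataclass
class CallSegment:
    onset: float
    offset: float
    click_count: int


def call_segmentation(train: EventTrain, gap_s: float = 0.5) -> list:
    """Split a train into calls at inter-event gaps of at least ``gap_s``.

    Calls are maximal runs of events whose consecutive gaps are below the
    threshold; per-call counts conserve the total number of events.
    """
    if gap_s <= 0:
        raise ValidationError("gap_s must be positive")
    if len(train) == 0:
        return []
    cut = np.flatnonzero(np.diff(train.times) >= gap_s)
    starts = np.concatenate([[0], cut + 1])
    stops = np.concatenate([cut + 1, [len(train)]])
    return [CallSegment(onset=float(train.times[a]), offset=float(train.times[b - 1]),
                        click_count=int(b - a))
            for a, b in zip(starts, stops)]


# ---------------------------------------------------------------------------
# Gaussian rate models
# ---------------------------------------------------------------------------

@dataclass
class RateModelFit:
    """Unimodal/bimodal Gaussian fit to a normalized rate histogram.

    ``components`` holds (mu, sigma, amp) triples sorted by mu ascending;
    ``sse`` is the squared error on the histogram heights and ``r`` the
    correlation between fitted and observed heights.
    """

    modality: str
    components: list
    sse: float
    r: float

    @property
    def mus(self) -> list:
        return [c[0] for c in self.components]


def _gauss(x, mu, sigma, amp):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def _gauss2(x, mu1, s1, a1, mu2, s2, a2):
    return _gauss(x, mu1, s1, a1) + _gauss(x, mu2, s2, a2)


def _weighted_moments(x, y):
    w = y / y.sum()
    mu = float(np.sum(w * x))
    sd = float(np.sqrt(np.sum(w * (x - mu) ** 2)))
    return mu, max(sd, 0.5)


def _bimodal_starts(x, y):
    """Candidate (mu1, mu2) start pairs: two highest local maxima separated
    by at least 10 Hz, falling back to the 33/66% weighted quantiles."""
    starts = []
    pk, props = sps.find_peaks(y, height=0.0)
    if pk.size >= 2:
        order = pk[np.argsort(props["peak_heights"])[::-1]]
        first = order[0]
        for second in order[1:]:
            if abs(x[second] - x[first]) >= 10.0:
                starts.append((float(x[first]), float(x[second])))
                break
    cdf = np.cumsum(y) / y.sum()
    q = lambda f: float(x[np.searchsorted(cdf, f)])
    starts.append((q(0.33), q(0.66)))
    return starts


def fit_rate_model(hist: RateHistogram, modality: str) -> RateModelFit:
    """Least-squares Gaussian fit to histogram heights vs bin centers.

    ``modality`` is ``"unimodal"`` (one component) or ``"bimodal"`` (sum of
    two). Amplitudes are free parameters; multistart initialization guards
    against bad local minima. A bimodal fit that collapses onto a single
    mode raises :class:`DegenerateFitWarning` rather than silently
    reporting a spurious second component.
    """
    x = hist.centers
    y = hist.heights
    if y.sum() <= 0:
        raise InsufficientEventsError("empty histogram")
    if modality not in ("unimodal", "bimodal"):
        raise ValidationError("modality must be 'unimodal' or 'bimodal'")
    if modality == "bimodal" and np.count_nonzero(y) < 6:
        raise ValidationError("bimodal fit requires at least 6 nonzero bins")

    span = float(x[-1] - x[0]) or 1.0
    best = None
    attempts = []
    if modality == "unimodal":
        mu0 = float(x[int(np.argmax(y))])
        _, sd0 = _weighted_moments(x, y)
        attempts.append(([mu0, sd0, float(y.max())], _gauss))
        mu_w, sd_w = _weighted_moments(x, y)
        attempts.append(([mu_w, sd_w, float(y.max())], _gauss))
    else:
        _, sd0 = _weighted_moments(x, y)
        sd0 = max(sd0 / 2.0, 0.5)
        for mu1, mu2 in _bimodal_starts(x, y):
            a1 = float(y[np.argmin(np.abs(x - mu1))])
            a2 = float(y[np.argmin(np.abs(x - mu2))])
            attempts.append(([mu1, sd0, max(a1, 1e-3), mu2, sd0, max(a2, 1e-3)],
                             _gauss2))

    lo_mu, hi_mu = float(x[0] - 5), float(x[-1] + 5)
    for p0, model in attempts:
        k = len(p0) // 3
        lower = [lo_mu, 1e-3, 0.0] * k
        upper = [hi_mu, span, 10.0 * max(float(y.max()), 1e-9)] * k
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lower, upper),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = y - model(x, *popt)
        sse = float(np.sum(resid ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, model)
    if best is None:
        raise FitFailureError("Gaussian fit failed from every start",
                              partial=attempts[0][0] if attempts else None)

    sse, popt, model = best
    yhat = model(x, *popt)
    if np.std(yhat) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, yhat)[0, 1])
    else:
        r = 0.0
    comps = sorted(
        [tuple(float(v) for v in popt[i:i + 3]) for i in range(0, len(popt), 3)],
        key=lambda c: c[0])
    if modality == "bimodal":
        (mu1, s1, a1), (mu2, s2, a2) = comps
        amps = sorted([a1, a2])
        if abs(mu2 - mu1) < max(s1, s2) or amps[0] < 0.1 * amps[1]:
            warnings.warn(
                "bimodal fit is degenerate: components overlap or the minor "
                "component is negligible; the histogram is effectively unimodal",
                DegenerateFitWarning, stacklevel=2)
    return RateModelFit(modality=modality, components=comps, sse=sse, r=r)
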