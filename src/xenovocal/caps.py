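"""Compound-action-potential detection and fictive-call segmentation.

CAPs are treated as unitary population events: detection finds local maxima
of a short moving average of |x| above a robust threshold, then refines each
event to the raw |x| peak within ±1.5 ms. Fictive calls are maximal runs of
CAPs separated by less than a gap threshold, and each call is divided into
fast (>50 Hz), slow (<35 Hz) and unlabeled phases from its inter-CAP
intervals, with median-of-3 label smoothing so a single jittered interval
does not fragment a trill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import _robust_threshold, classify_rate
from .errors import ValidationError
from .events import LABEL_FAST, LABEL_SLOW, LABEL_UNLABELED, EventTrain
from .recording import ROLE_LEFT_NERVE


def detection_traces(x: np.ndarray, sample_rate: float, threshold_k: float,
                     smooth_ms: float):
    """Rectified trace, smoothed detection trace, and robust threshold.

    The threshold is median + k*MAD of the raw |x| trace; candidate peaks
    are taken on the short moving average, whose noise floor sits far below
    that threshold while CAP peaks remain well above it.
    """
    a = np.abs(x)
    win = max(1, int(round(smooth_ms * 1e-3 * sample_rate)))
    det = sps.convolve(a, np.ones(win) / win, mode="same") if win > 1 else a
    return a, det, _robust_threshold(a, threshold_k)


def detect_caps(nerve: np.ndarray, sample_rate: float, threshold_k: float = 6.0,
                refractory_ms: float = 3.0, smooth_ms: float = 1.0,
                channel_role: str = ROLE_LEFT_NERVE) -> EventTrain:
    """Detect CAPs in a nerve trace.

    Candidate events are local maxima of the ``smooth_ms`` moving average of
    |x| exceeding median + ``threshold_k``·MAD of |x|, separated by at least
    ``refractory_ms``. Each event's time and amplitude are the raw |x| peak
    within ±1.5 ms of the candidate. An all-zero trace yields an empty train.
    """
    if refractory_ms <= 0:
        raise ValidationError("refractory_ms must be positive")
    x = np.asarray(nerve, dtype=float)
    empty = EventTrain(np.empty(0), np.empty(0), channel_role=channel_role)
    if x.size == 0:
        return empty
    a, det, thr = detection_traces(x, sample_rate, threshold_k, smooth_ms)
    dist = max(1, int(round(refractory_ms * 1e-3 * sample_rate)))
    peaks, _ = sps.find_peaks(det, height=thr, distance=dist)
    if peaks.size == 0:
        return empty

    half = max(1, int(round(1.5e-3 * sample_rate)))
    refined, amps = [], []
    for p in peaks:
        lo, hi = max(0, p - half), min(a.size, p + half + 1)
        idx = lo + int(np.argmax(a[lo:hi]))
        refined.append(idx)
        amps.append(float(a[idx]))
    # refinement can merge neighbours; keep the larger of colliding events
    order = np.argsort(refined)
    times, out_amps = [], []
    for k in order:
        idx, amp = refined[k], amps[k]
        if times and idx - times[-1] < dist:
            if amp > out_amps[-1]:
                times[-1], out_amps[-1] = idx, amp
            continue
        times.append(idx)
        out_amps.append(amp)
    return EventTrain(times=np.asarray(times) / sample_rate,
                      amplitudes=np.asarray(out_amps),
                      channel_role=channel_role)


@dataclass
class Phase:
    """A maximal run of identically labeled inter-CAP intervals."""

    label: str
    onset: float
    offset: float
    cap_count: int
    mean_rate: float  # (cap_count - 1) / duration, Hz
    first_index: int = 0  # index of the phase's first CAP within the call train


@dataclass
class FictiveCall:
    """One fictive call: its CAP train and fast/slow/unlabeled phases."""

    onset: float
    offset: float
    train: EventTrain
    phases: list = field(default_factory=list)

    @property
    def cap_count(self) -> int:
        return len(self.train)


def _smooth_labels(labels: list) -> list:
    """Median-of-3 smoothing on interval labels (slow<unlabeled<fast order)
    so an isolated one-interval flip does not split a phase."""
    code = {LABEL_SLOW: 0, LABEL_UNLABELED: 1, LABEL_FAST: 2}
    inv = {v: k for k, v in code.items()}
    c = [code[l] for l in labels]
    if len(c) < 3:
        return list(labels)
    out = list(c)
    for i in range(1, len(c) - 1):
        out[i] = int(np.median(c[i - 1:i + 2]))
    return [inv[v] for v in out]


def _runs(labels: list) -> list:
    """(label, start, stop_exclusive) runs over interval indices."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


_MIN_RUN_INTERVALS = 3  # shorter label runs are absorbed by their neighbour


def _merge_short_runs(runs: list) -> list:
    """Absorb runs shorter than 3 intervals into their neighbouring phase,
    coalescing equal-label neighbours, so a brief excursion of a few jittery
    intervals does not fragment a trill. A lone short run is kept."""
    merged: list = []
    for lab, s, e in runs:
        if not merged:
            merged.append((lab, s, e))
        elif e - s < _MIN_RUN_INTERVALS:
            plab, ps, _ = merged[-1]
            merged[-1] = (plab, ps, e)
        elif merged[-1][2] - merged[-1][1] < _MIN_RUN_INTERVALS and \
                len(merged) == 1:
            merged[-1] = (lab, merged[-1][1], e)  # leading stub joins this run
        elif merged[-1][0] == lab:
            merged[-1] = (lab, merged[-1][1], e)
        else:
            merged.append((lab, s, e))
    return merged


def _fold_sandwiched_unlabeled(runs: list) -> list:
    """Fold unlabeled (35-50 Hz) interludes flanked by one and the same
    fast/slow label into that phase: within a trill they are rate jitter
    through the band the disjoint definitions leave out, not a phase."""
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            lab = runs[i - 1][0]
            if runs[i][0] == LABEL_UNLABELED and lab == runs[i + 1][0] \
                    and lab != LABEL_UNLABELED:
                runs = runs[:i - 1] + [(lab, runs[i - 1][1], runs[i + 1][2])] \
                    + runs[i + 2:]
                changed = True
                break
    return runs


def segment_fictive_calls(train: EventTrain, gap_s: float = 0.5,
                          smooth: bool = True) -> list:
    """Segment a CAP train into calls and label their phases.

    Within each call every inter-CAP interval is labeled by its
    instantaneous rate; phases are maximal runs of identically labeled
    intervals (after optional median-of-3 smoothing, with single-interval
    runs merged into their predecessor). Boundary CAPs are assigned to the
    earlier phase so phase CAP counts sum to the call CAP count.
    """
    if gap_s <= 0:
        raise ValidationError("gap_s must be positive")
    calls = []
    if len(train) == 0:
        return calls
    cut = np.flatnonzero(np.diff(train.times) >= gap_s)
    starts = np.concatenate([[0], cut + 1])
    stops = np.concatenate([cut + 1, [len(train)]])
    for a, b in zip(starts, stops):
        sub = train.slice(int(a), int(b))
        call = FictiveCall(onset=float(sub.times[0]), offset=float(sub.times[-1]),
                           train=sub)
        if len(sub) >= 2:
            rates = 1.0 / np.diff(sub.times)
            labels = [classify_rate(r) for r in rates]
            if smooth:
                labels = _smooth_labels(labels)
            runs = _fold_sandwiched_unlabeled(_merge_short_runs(_runs(labels)))
            for k, (lab, s, e) in enumerate(runs):
                last = k == len(runs) - 1
                cap_hi = e + 1 if last else e  # boundary CAP -> earlier phase
                count = cap_hi - s
                onset, offset = float(sub.times[s]), float(sub.times[e])
                dur = offset - onset
                call.phases.append(Phase(
                    label=lab, onset=onset, offset=offset, cap_count=int(count),
                    mean_rate=float((e - s) / dur) if dur > 0 else np.nan,
                    first_index=int(s)))
        calls.append(call)
    return calls
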