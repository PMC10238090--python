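"""Maximum-lag-time statistic between the left and right laryngeal nerves.

The synchrony statistic slides one raw nerve trace against the other over a
bounded lag grid (±10 ms by default; ±50 ms for the female release-call
preset, whose CAPs are much wider) and reports the lag of the maximum
Pearson correlation, computed on the segment spanning 10 consecutive CAPs
of the reference channel plus a 5 ms margin. A positive maximum lag time
means the comparison (typically transected-side) channel lags the
reference (intact-side) channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .caps import detect_caps, segment_fictive_calls
from .errors import InsufficientEventsError, PairingError, ValidationError
from .recording import ROLE_LEFT_NERVE, ROLE_RIGHT_NERVE, Recording
from .stats import wilcoxon_signed_rank

logger = logging.getLogger(__name__)

DEFAULT_BOUND_MS = 10.0
FEMALE_RELEASE_BOUND_MS = 50.0


@dataclass
class LagResult:
    """Cross-correlation coefficient vs lag and the maximum-lag statistic."""

    lags_ms: np.ndarray  # symmetric grid, step = 1/sample_rate
    coeffs: np.ndarray  # Pearson correlation per lag, in [-1, 1]
    max_lag_ms: float
    window: tuple  # (start, end) seconds of the reference segment
    n_caps: int
    at_bound: bool = False


def _other_nerve(reference: str) -> str:
    if reference == ROLE_LEFT_NERVE:
        return ROLE_RIGHT_NERVE
    if reference == ROLE_RIGHT_NERVE:
        return ROLE_LEFT_NERVE
    raise ValidationError(f"reference must be a nerve role, got {reference!r}")


def default_bound_ms(rec: Recording) -> float:
    """±10 ms, widened to ±50 ms for the female release-call preset."""
    if rec.meta.get("profile") == "X_laevis_female_release":
        return FEMALE_RELEASE_BOUND_MS
    return DEFAULT_BOUND_MS


def max_lag(rec: Recording, reference: str = ROLE_LEFT_NERVE,
            window_caps: int = 10, bound_ms: float = DEFAULT_BOUND_MS,
            cap_train=None, start_index: int = 0,
            margin_ms: float = 5.0) -> LagResult:
    """Maximum-lag-time statistic over one window of consecutive CAPs.

    The raw-trace segment spanning ``window_caps`` consecutive CAPs of the
    reference channel (± ``margin_ms``) is correlated against the comparison
    channel shifted by every integer-sample lag in ±``bound_ms``. Ties in
    the argmax break toward the smaller |lag|; a result at the grid edge is
    flagged ``at_bound``.
    """
    fs = rec.sample_rate
    x_ref = rec.channel(reference)
    x_cmp = rec.channel(_other_nerve(reference))
    train = cap_train if cap_train is not None else detect_caps(x_ref, fs)
    if len(train) < start_index + window_caps:
        raise InsufficientEventsError(
            f"need {window_caps} CAPs on {reference}, have "
            f"{len(train) - start_index}")
    sel = train.times[start_index:start_index + window_caps]
    i0 = int(round((sel[0] - margin_ms * 1e-3) * fs))
    i1 = int(round((sel[-1] + margin_ms * 1e-3) * fs)) + 1
    lag_n = int(round(bound_ms * 1e-3 * fs))
    if lag_n < 1:
        raise ValidationError("bound_ms smaller than one sample period")
    if i0 - lag_n < 0 or i1 + lag_n > rec.n_samples:
        raise ValidationError(
            "lag bound exceeds the margin available around the CAP window")

    ref = x_ref[i0:i1]
    ref = ref - ref.mean()
    ref_norm = np.sqrt(np.sum(ref ** 2))
    lags = np.arange(-lag_n, lag_n + 1)
    coeffs = np.empty(lags.size)
    for j, k in enumerate(lags):
        seg = x_cmp[i0 + k:i1 + k]
        seg = seg - seg.mean()
        denom = ref_norm * np.sqrt(np.sum(seg ** 2))
        coeffs[j] = float(np.dot(ref, seg) / denom) if denom > 0 else 0.0

    best = coeffs.max()
    cand = lags[coeffs >= best - 1e-12]
    k_star = int(cand[np.argmin(np.abs(cand))])  # ties -> smaller |lag|
    return LagResult(lags_ms=lags / fs * 1e3, coeffs=coeffs,
                     max_lag_ms=float(k_star / fs * 1e3),
                     window=(i0 / fs, i1 / fs), n_caps=window_caps,
                     at_bound=abs(k_star) == lag_n)


def lag_by_phase(rec: Recording, reference: str = ROLE_LEFT_NERVE,
                 window_caps: int = 10, bound_ms: float | None = None,
                 gap_s: float = 0.5) -> dict:
    """One LagResult per (call, phase) with at least ``window_caps`` CAPs.

    Returns a map phase label -> list of LagResult. Phases shorter than the
    window are skipped with a logged notice.
    """
    if bound_ms is None:
        bound_ms = default_bound_ms(rec)
    fs = rec.sample_rate
    train = detect_caps(rec.channel(reference), fs, channel_role=reference)
    out: dict = {}
    for call in segment_fictive_calls(train, gap_s=gap_s):
        base = int(np.searchsorted(train.times, call.train.times[0]))
        for phase in call.phases:
            if phase.cap_count < window_caps:
                logger.info("skipping %s phase at %.3f s: %d CAPs < window %d",
                            phase.label, phase.onset, phase.cap_count, window_caps)
                continue
            res = max_lag(rec, reference=reference, window_caps=window_caps,
                          bound_ms=bound_ms, cap_train=train,
                          start_index=base + phase.first_index)
            out.setdefault(phase.label, []).append(res)
    return out


def lag_change(pre, post):
    """Mean paired change in maximum lag time plus a Wilcoxon comparison.

    ``pre`` and ``post`` are paired per-brain values (floats or
    :class:`LagResult`), same subjects in the same order. Returns
    ``(delta_ms, test_summary)`` with ``delta_ms = mean(post) - mean(pre)``.
    """
    def vals(seq):
        return np.array([v.max_lag_ms if isinstance(v, LagResult) else float(v)
                         for v in seq])

    a, b = vals(pre), vals(post)
    if a.size != b.size:
        raise PairingError(f"pre ({a.size}) and post ({b.size}) are not paired")
    if a.size == 0:
        raise PairingError("empty paired lists")
    delta = float(b.mean() - a.mean())
    summary = wilcoxon_signed_rank(b, a)
    return delta, summary
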