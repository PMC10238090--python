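"""Point-event containers for detected clicks and compound action potentials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

LABEL_FAST = "fast"
LABEL_SLOW = "slow"
LABEL_UNLABELED = "unlabeled"

PHASE_LABELS = (LABEL_FAST, LABEL_SLOW, LABEL_UNLABELED)


@dataclass
class EventTrain:
    """Detected point events (clicks or CAPs) on one channel.

    ``times`` are event peak times in seconds, strictly increasing;
    ``amplitudes`` are the corresponding peak (or envelope) magnitudes.
    ``labels`` optionally tags each event with a phase label
    (fast / slow / unlabeled).
    """

    times: np.ndarray
    amplitudes: np.ndarray
    channel_role: str = "audio"
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValidationError("times and amplitudes must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("event times must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != self.times.size:
                raise ValidationError("labels must match times in length")

    def __len__(self) -> int:
        return self.times.size

    def slice(self, start: int, stop: int) -> "EventTrain":
        """Sub-train of events with index in [start, stop)."""
        return EventTrain(
            times=self.times[start:stop],
            amplitudes=self.amplitudes[start:stop],
            channel_role=self.channel_role,
            labels=None if self.labels is None else self.labels[start:stop],
        )
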