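"""Multichannel, uniformly sampled electrophysiology/audio container.

A :class:`Recording` bundles one or more equal-length channels (identified by
role: left/right laryngeal nerve, parabrachial-nucleus LFP, or call audio),
the sample rate, optional stimulus event times, and a metadata map. The
synthetic generators store ground truth (event times, imposed lags, phase
spans) in ``meta`` so downstream estimators can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingChannelError, ValidationError

ROLE_LEFT_NERVE = "left_nerve"
ROLE_RIGHT_NERVE = "right_nerve"
ROLE_PBN_LFP = "pbn_lfp"
ROLE_AUDIO = "audio"

#: Channel roles accepted by the container, in conventional order.
CHANNEL_ROLES = (ROLE_LEFT_NERVE, ROLE_RIGHT_NERVE, ROLE_PBN_LFP, ROLE_AUDIO)

NERVE_ROLES = (ROLE_LEFT_NERVE, ROLE_RIGHT_NERVE)


@dataclass
class Recording:
    """Uniformly sampled multichannel recording.

    Parameters
    ----------
    sample_rate : float
        Samples per second (Hz). Electrophysiology defaults to 10 kHz.
    channels : dict[str, numpy.ndarray]
        Mapping role -> signal. Insertion order is the channel order. All
        signals must have equal length and roles must be drawn from
        :data:`CHANNEL_ROLES`.
    stim_times : numpy.ndarray
        Stimulus onset times in seconds, strictly increasing, within the
        recording. May be empty.
    meta : dict
        Free-form provenance map (seed, profile name, scenario, ground-truth
        event times, imposed lags, ...).
    """

    sample_rate: float
    channels: dict
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        clean = {}
        n = None
        for role, sig in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValidationError(
                    f"unknown channel role {role!r}; valid roles: {CHANNEL_ROLES}"
                )
            sig = np.asarray(sig, dtype=float)
            if sig.ndim != 1:
                raise ValidationError(f"channel {role!r} must be 1-D")
            if n is None:
                n = sig.size
            elif sig.size != n:
                raise ValidationError("all channels must have equal length")
            clean[role] = sig
        self.channels = clean
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValidationError("stim_times must be strictly increasing")
            if self.stim_times[0] < 0 or self.stim_times[-1] > self.duration:
                raise ValidationError("stim_times must lie within [0, duration]")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sample_rate

    # -- access ------------------------------------------------------------
    def has_channel(self, role: str) -> bool:
        return role in self.channels

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise MissingChannelError(
                f"recording has no {role!r} channel (present: {list(self.channels)})"
            ) from None

    def nerve_roles(self) -> list:
        """Nerve channel roles present, left before right."""
        return [r for r in NERVE_ROLES if r in self.channels]
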