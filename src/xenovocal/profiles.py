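"""Species presets for the synthetic-data generators.

Each :class:`SpeciesProfile` captures the click-rate statistics of one of the
study animals: the advertisement calls of *X. amieti* and *X. cliivi* are
monophasic fast (clicks only above 50 Hz), *X. tropicalis* is monophasic slow
(below 35 Hz), *X. petersii* and male *X. laevis* are biphasic (a fast trill
followed by a slow trill). Female *X. laevis* release calls and the
"long-slow" calls of the fast-click species cover the 6–20 Hz range.

Rate means are the measured in-vivo means for each species; the synapse
presets carry the potentiation/attenuation time constants (in stimulus
pulses) measured for parabrachial-evoked compound action potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import UnknownProfileError, ValidationError

CALL_MONO_FAST = "monophasic_fast"
CALL_MONO_SLOW = "monophasic_slow"
CALL_BIPHASIC = "biphasic"

#: Operational rate cutoffs: clicks/CAPs above 50 Hz are "fast", below 35 Hz
#: "slow"; the 35–50 Hz band is deliberately left unlabeled.
FAST_CUTOFF_HZ = 50.0
SLOW_CUTOFF_HZ = 35.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Click-train statistics of one species/sex/treatment group."""

    name: str
    call_type: str
    fast_rate_mean: float | None = None  # Hz
    fast_rate_sd: float | None = None  # Hz
    slow_rate_mean: float | None = None  # Hz
    slow_rate_sd: float | None = None  # Hz
    clicks_per_phase_mean: int = 30
    phase_order: tuple = ("fast",)
    click_carrier_freq: float = 2000.0  # Hz, audio clicks only

    def __post_init__(self):
        if self.call_type not in (CALL_MONO_FAST, CALL_MONO_SLOW, CALL_BIPHASIC):
            raise ValidationError(f"unknown call_type {self.call_type!r}")
        has_fast = self.fast_rate_mean is not None
        has_slow = self.slow_rate_mean is not None
        if self.call_type == CALL_BIPHASIC and not (has_fast and has_slow):
            raise ValidationError("biphasic profiles need both rate components")
        if self.call_type != CALL_BIPHASIC and (has_fast == has_slow):
            raise ValidationError("monophasic profiles define exactly one component")
        if has_fast and self.fast_rate_mean <= FAST_CUTOFF_HZ:
            raise ValidationError("fast_rate_mean must exceed the 50 Hz fast cutoff")
        # Slow components sit below the fast cutoff. (The male X. laevis slow
        # trill, 38.4 Hz, falls in the 35-50 Hz unlabeled band.)
        if has_slow and self.slow_rate_mean >= FAST_CUTOFF_HZ:
            raise ValidationError("slow_rate_mean must be below the 50 Hz fast cutoff")

    def phase_rate(self, label: str) -> tuple:
        """(mean, sd) of the click rate for a phase label."""
        if label == "fast":
            if self.fast_rate_mean is None:
                raise ValidationError(f"{self.name} has no fast component")
            return self.fast_rate_mean, self.fast_rate_sd or 0.0
        if label == "slow":
            if self.slow_rate_mean is None:
                raise ValidationError(f"{self.name} has no slow component")
            return self.slow_rate_mean, self.slow_rate_sd or 0.0
        raise ValidationError(f"unknown phase label {label!r}")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["phase_order"] = list(self.phase_order)
        return d


_PRESETS = {
    "X_amieti": SpeciesProfile(
        name="X_amieti", call_type=CALL_MONO_FAST,
        fast_rate_mean=143.0, fast_rate_sd=5.0,
        clicks_per_phase_mean=60, phase_order=("fast",),
        click_carrier_freq=3500.0,
    ),
    "X_cliivi": SpeciesProfile(
        name="X_cliivi", call_type=CALL_MONO_FAST,
        fast_rate_mean=59.82, fast_rate_sd=5.0,
        clicks_per_phase_mean=40, phase_order=("fast",),
        click_carrier_freq=2500.0,
    ),
    "X_tropicalis": SpeciesProfile(
        name="X_tropicalis", call_type=CALL_MONO_SLOW,
        slow_rate_mean=31.9, slow_rate_sd=3.0,
        clicks_per_phase_mean=20, phase_order=("slow",),
        click_carrier_freq=1500.0,
    ),
    "X_petersii": SpeciesProfile(
        name="X_petersii", call_type=CALL_BIPHASIC,
        fast_rate_mean=69.9, fast_rate_sd=3.0,
        slow_rate_mean=31.3, slow_rate_sd=3.0,
        clicks_per_phase_mean=30, phase_order=("fast", "slow"),
        click_carrier_freq=2200.0,
    ),
    "X_laevis_male": SpeciesProfile(
        name="X_laevis_male", call_type=CALL_BIPHASIC,
        fast_rate_mean=58.3, fast_rate_sd=2.5,
        slow_rate_mean=38.4, slow_rate_sd=3.0,
        clicks_per_phase_mean=30, phase_order=("fast", "slow"),
        click_carrier_freq=1800.0,
    ),
    "X_laevis_female_release": SpeciesProfile(
        name="X_laevis_female_release", call_type=CALL_MONO_SLOW,
        slow_rate_mean=6.0, slow_rate_sd=1.0,
        clicks_per_phase_mean=15, phase_order=("slow",),
        click_carrier_freq=1200.0,
    ),
    "X_laevis_Tfemale": SpeciesProfile(
        name="X_laevis_Tfemale", call_type=CALL_BIPHASIC,
        fast_rate_mean=55.0, fast_rate_sd=2.5,
        slow_rate_mean=30.0, slow_rate_sd=3.0,
        clicks_per_phase_mean=30, phase_order=("fast", "slow"),
        click_carrier_freq=1800.0,
    ),
    "X_laevis_long_slow": SpeciesProfile(
        name="X_laevis_long_slow", call_type=CALL_MONO_SLOW,
        slow_rate_mean=13.0, slow_rate_sd=3.0,
        clicks_per_phase_mean=20, phase_order=("slow",),
        click_carrier_freq=2500.0,
    ),
}

PROFILE_NAMES = tuple(_PRESETS)


def make_species_profile(name: str) -> SpeciesProfile:
    """Return the preset profile for ``name``.

    Raises
    ------
    UnknownProfileError
        If the name is not one of :data:`PROFILE_NAMES`.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownProfileError(
            f"unknown species profile {name!r}; valid names: {', '.join(PROFILE_NAMES)}"
        ) from None


@dataclass(frozen=True)
class SynapseParams:
    """Parameters of the parabrachial-to-motoneuron evoked-CAP model.

    Under a stimulus train at frequency above ``min_freq``, the t-th pulse
    evokes (with probability ``1 - failure_prob``) a CAP whose peak amplitude
    has mean ``C_amp + A_amp * (1 - exp(-t/tau_amp))**a_amp`` and whose peak
    latency has mean ``C_lat + (L0 - C_lat) * exp(-t/tau_lat)**a_lat`` after
    stimulus onset. Taus are in units of stimulus pulses.
    """

    A_amp: float = 300.0  # uV, amplitude asymptote above baseline
    tau_amp: float = 6.90  # pulses
    a_amp: float = 1.0
    C_amp: float = 20.0  # uV, first-pulse baseline
    L0: float = 12.0  # ms, initial latency
    tau_lat: float = 3.64  # pulses
    a_lat: float = 1.0
    C_lat: float = 6.5  # ms, plateau latency
    min_freq: float = 10.0  # Hz; below this no CAPs are evoked
    failure_prob: float = 0.0
    noise_sd_amp: float = 0.0  # uV
    noise_sd_lat: float = 0.0  # ms

    def __post_init__(self):
        if self.tau_amp <= 0 or self.tau_lat <= 0:
            raise ValidationError("time constants must be positive")
        if self.A_amp <= 0 or self.C_lat <= 0:
            raise ValidationError("A_amp and C_lat must be positive")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValidationError("failure_prob must be in [0, 1]")
        if self.L0 < self.C_lat:
            raise ValidationError("initial latency must not be below the plateau")


#: Evoked-CAP model presets: male X. laevis taus and the pooled taus of the
#: other fast-click species.
SYNAPSE_PRESETS = {
    "X_laevis_male": SynapseParams(tau_amp=6.90, tau_lat=3.64),
    "fast_clickers_pooled": SynapseParams(tau_amp=5.15, tau_lat=2.69),
}
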