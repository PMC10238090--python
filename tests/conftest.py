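import pytest
from hypothesis import HealthCheck, settings

import xenovocal as xv

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def amieti_audio():
    """Two synthetic X. amieti calls (monophasic fast, 143 Hz preset)."""
    return xv.synth_call_audio("X_amieti", n_calls=2, seed=11)


@pytest.fixture(scope="session")
def petersii_fictive():
    """Biphasic X. petersii fictive recording, LFP phase-locked to fast CAPs."""
    return xv.synth_fictive_recording("X_petersii", n_calls=1, seed=21)


@pytest.fixture(scope="session")
def clean_stim():
    """Noiseless 30-pulse, 30 Hz stimulus-response recording."""
    params = xv.SYNAPSE_PRESETS["X_laevis_male"]
    return xv.synth_stim_response(params, stim_freq=30.0, n_pulses=30,
                                  seed=31, trace_snr=None)
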