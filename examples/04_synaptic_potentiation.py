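"""Evoked-CAP potentiation under repetitive parabrachial stimulation.

A 30 Hz stimulus train evokes CAPs whose amplitude potentiates and whose
latency shortens with pulse order, each following C + A(1-e^(-t/tau))^a
(latency as the equivalent falling form). The fits report tau in stimulus
pulses; round(tau * ln 20) is the pulse count to reach 95% of the change.
"""

import xenovocal as xv

params = xv.SYNAPSE_PRESETS["X_laevis_male"]  # tau_amp 6.90, tau_lat 3.64
rec = xv.synth_stim_response(params, stim_freq=30.0, n_pulses=30, seed=4,
                             trace_snr=20.0)
series = xv.extract_stim_responses(rec)[0]

amp_fit = xv.fit_potentiation(series, "rising")
lat_fit = xv.fit_potentiation(series, "falling")
print(f"amplitude: tau = {amp_fit.tau:.2f} pulses (generator {params.tau_amp}),"
      f" r = {amp_fit.r:.3f}")
print(f"latency:   tau = {lat_fit.tau:.2f} pulses (generator {params.tau_lat}),"
      f" r = {lat_fit.r:.3f}")
print(f"95% of amplitude reached in {xv.pulses_to_fraction(amp_fit.tau)} pulses,"
      f" 95% of latency change in {xv.pulses_to_fraction(lat_fit.tau)} pulses")
print(f"plateau latency after pulse 15: {xv.plateau_latency(series):.2f} ms "
      f"(generator plateau {params.C_lat} ms)")

trials = []
for f in (5.0, 10.0, 20.0, 30.0):
    r = xv.synth_stim_response(params, stim_freq=f, n_pulses=20, seed=5)
    trials.extend(xv.extract_stim_responses(r))
print(f"minimum effective stimulus frequency: "
      f"{xv.min_effective_frequency(trials):g} Hz (generator threshold "
      f"{params.min_freq:g} Hz; below it no CAPs are evoked)")
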