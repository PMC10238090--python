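"""Click-rate characterization of synthetic advertisement-call audio.

Builds calls from two species presets, detects clicks on the amplitude
envelope, and fits Gaussian models to the 1-Hz-binned instantaneous-rate
histograms: unimodal for the monophasic X. amieti call, bimodal for the
biphasic X. petersii call. The fitted mu values estimate each species'
characteristic click rate(s) in Hz.
"""

import xenovocal as xv

for name, modality in [("X_amieti", "unimodal"), ("X_petersii", "bimodal")]:
    profile = xv.make_species_profile(name)
    rec = xv.synth_call_audio(profile, n_calls=5, seed=1)
    train = xv.detect_clicks(xv.envelope(rec), rec.sample_rate)
    rates = xv.rates_by_call(train)
    fit = xv.fit_rate_model(xv.rate_histogram(rates), modality)
    expected = [v for v in (profile.slow_rate_mean, profile.fast_rate_mean)
                if v is not None]
    print(f"{name}: {len(train)} clicks detected "
          f"({len(rec.meta['click_times'])} generated)")
    print(f"  fitted mu(s): {[round(m, 2) for m in fit.mus]} Hz "
          f"(generator means: {expected} Hz, fit r = {fit.r:.3f})")

print("\nEach mu is the center of one Gaussian component of the click-rate")
print("histogram; recovering the preset means validates the pipeline.")
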