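# Methods

This note documents the models behind `xenovocal`: what the synthetic
generators emulate, how each estimator works, the defaults that matter, and
the numerical choices made where the design was open.

## Signals and conventions

Electrophysiology is sampled at 10 kHz (nerve traces conceptually band-passed
10 Hz–10 kHz, LFP 0.1 Hz–10 kHz), audio at 44.1 kHz. Times are seconds
internally; all reported lags and latencies are milliseconds. Intervals are
half-open `[onset, offset)`. Event rates classify as *fast* above 50 Hz and
*slow* below 35 Hz; the 35–50 Hz band is deliberately unlabeled, mirroring
the disjoint operational definitions used for the recordings. All randomness
flows through `numpy.random.default_rng(seed)`, so identical seeds give
bit-identical recordings.

## Synthetic-data generator

The generator is phenomenological: it reproduces the statistical structure
the estimators rely on, not the biophysics of the underlying circuits.

**Species presets.** Click-rate means are the measured in-vivo means per
species: 143.0 Hz (*X. amieti*), 59.82 Hz (*X. cliivi*), 31.9 Hz
(*X. tropicalis*), 69.9/31.3 Hz (*X. petersii*, fast/slow), 58.3/38.4 Hz
(male *X. laevis*). Groups without printed rate values were chosen once:
female release calls at 6 Hz, "long-slow" calls at 13 Hz (the 6–20 Hz band),
and testosterone-treated females at 55/30 Hz (their LFP spectra peak between
50 and 60 Hz). Rate spreads (sd 2.5–5 Hz) are set so that histogram-model
recovery at ~2000 intervals resolves means to well under 1 Hz. Note that the
male *X. laevis* slow trill (38.4 Hz) sits inside the unlabeled 35–50 Hz
band, so its second phase is reported as `unlabeled` by the classifier —
a faithful consequence of the disjoint definitions.

**Click trains and audio.** Inter-click intervals are `1/rate` with
`rate ~ Normal(mean, sd)` truncated at 1 Hz by redraw (the histogram's bin
floor). Each audio click is a damped sinusoid (4 ms, 1 ms decay) at the
species' carrier frequency on white noise; default click-peak SNR is 10.
Calls are separated by 1 s of silence, with a 0.5 s call-free lead-in.

**CAP waveform.** A difference of Gaussians, 2.5 ms total width, positive
peak first, with the trailing negative lobe scaled to 0.6 of the positive
peak. The asymmetry is deliberate: with equal lobes the |x| maximum flips
between lobes under noise, adding ~0.5 ms timing jitter to every detected
event; real CAPs are asymmetric, and the 0.6 ratio makes the positive peak
the unambiguous fiducial. Nerve background noise is Gaussian, high-passed at
10 Hz (edge transients trimmed), at peak SNR 10 by default.

**Transection scenario.** Left and right nerves carry identical CAP
sequences; the right channel's CAP times are shifted by `lag_fast_ms` during
fast phases and `lag_slow_ms` during slow phases, plus optional per-CAP
jitter. Imposed lags are validated against the downstream ±10 ms search
window (±50 ms for the female release preset) since larger lags would be
undetectable. The demo's transection scenario uses a 1.53 ms fast-phase lag
and a 1.79 ms evoked-latency increase with 0.3 ms brain-to-brain jitter.

**LFP.** One sine cycle per driven CAP, spanning that CAP's interval (so the
oscillation frequency tracks the instantaneous CAP rate), on Gaussian noise.
Amplitudes are expressed relative to the 99th-percentile noise amplitude:
5× in `phasic_fast_only` mode (fast phases only), 1.2× in `weak` mode, none
in `silent` mode. The weak ratio sits well below the 2× activity rule
because the measured segment amplitude includes the noise floor riding on
the oscillation; 5× vs 1.2× makes the twice-noise rule separate the modes
cleanly.

**Evoked-CAP series.** Pulse t (1…n) of a train at frequency f evokes, with
probability `1 − failure_prob`, a CAP with mean amplitude
`C_amp + A_amp (1 − e^{−t/τ_amp})^{a_amp}` and mean latency
`C_lat + (L0 − C_lat) e^{−t/τ_lat}`, each with Gaussian noise; below
`min_freq` (default 10 Hz) no CAPs are evoked. Defaults are the male
*X. laevis* synapse preset (τ_amp = 6.90, τ_lat = 3.64 pulses, plateau
latency 6.5 ms); a pooled fast-clicker preset carries τ_amp = 5.15,
τ_lat = 2.69. Stimulus artifacts are not synthesized; stimulus times are
supplied as metadata, as the artifact shape in real recordings is
acquisition-specific.

## Estimators

**Click detection.** Full-wave rectification, 4th-order Butterworth low-pass
at 200 Hz (zero-phase), then peak picking above `median + 8·MAD` of the
envelope with a 4 ms refractory interval.

**CAP detection.** The threshold is `median + 6·MAD` of |x|. Candidate peaks
are found on a 1 ms moving average of |x| rather than on raw samples: the
robust threshold sits roughly 3 noise sigmas above zero, which raw |x|
excursions cross constantly (≈10 false events/s at any SNR), while the
smoothed trace's noise floor lies ~12 of its own sigmas below the same
threshold — and a genuine CAP still exceeds it several-fold. Each candidate
is then refined to the raw |x| argmax within ±1.5 ms, preserving
sample-exact peak times for latency measurements. When MAD degenerates to 0
(noiseless synthetic input) the threshold falls back to 10% of the trace
maximum, keeping detection scale-invariant.

**Phase segmentation.** Calls are maximal runs of CAPs with gaps < 0.5 s
(the slowest in-scope rate, 6 Hz, gives 167 ms intervals, so 0.5 s separates
calls without splitting slow trains). Within a call each inter-CAP interval
is labeled by its rate; labels get median-of-3 smoothing, label runs shorter
than 3 intervals are absorbed by their neighbouring phase, and an unlabeled
run flanked by one and the same fast/slow label is folded into that phase.
The last two rules exist because rate jitter alone (e.g. the *X. petersii*
slow trill at 31.3 ± 3 Hz puts ~11% of intervals above 35 Hz) would
otherwise fragment a contiguous trill; trills are treated as blocks.
Boundary CAPs belong to the earlier phase so phase counts sum to the call
count; `mean_rate = (cap_count − 1)/duration`.

**Maximum lag time.** Computed on the raw traces, not binarized event
trains — events only define the window: the segment spanning 10 consecutive
reference-channel CAPs plus 5 ms margin each side, so the full last CAP
waveform stays inside at every tested shift. Pearson correlation is
evaluated at every integer-sample lag in the ±bound grid; ties in the argmax
break toward the smaller |lag|, and results at the grid edge are flagged.
Positive lag means the comparison channel lags the reference. Per-phase
analysis takes the first 10 CAPs of each phase with at least 10; shorter
phases are skipped with a logged notice.

**LFP spectra.** One Hann-windowed periodogram per segment (no within-
segment averaging, which would change the resolution), normalized to its own
maximum; averages are taken only across equal-length segments and are not
re-normalized. The peak frequency is searched in 5–200 Hz, covering all
species' CAP rates. Activity classification uses the 99th percentile of |x|
as the amplitude measure (robust to isolated spikes) and the 2× baseline
rule.

**Potentiation fits.** Nonlinear least squares (`scipy.optimize.curve_fit`)
with multistart over τ ∈ {1, n/6, n/3, n}; the exponent a is fixed at 1 by
default — the 95%-rise arithmetic (6.90·ln 20 ≈ 21, 3.64·ln 20 ≈ 11,
2.69·ln 20 ≈ 8) is the a = 1 convention — with a ∈ {0.5, 1, 2} starts when
freed. Latency uses the falling form `C + A e^{−t/τ}` with A > 0, the same
family under reparameterization. Fits require ≥ 8 non-failure pulses and a
stimulus frequency above 10 Hz; a constant series returns a flagged
degenerate fit (A ≈ 0), and fitting the wrong direction is rejected by a
trend check (the amplitude term would need A < 0). `pulses_to_fraction`
rounds `−τ·ln(1 − f)` to the nearest integer, the only rule consistent with
all three reference pulse counts simultaneously (the pooled fast-clicker
amplitude τ of 5.15 gives round(5.15·ln 20) = 15 and is not used as a
reference count). The first pulse's response is often atypical and can be
excluded from fits by flag (included by default). Note that latencies read
off a 10 kHz trace are quantized to 0.1 ms, which bounds latency-τ recovery
at roughly ±0.12 pulses even without noise.

**Statistics.** The sign test is the exact two-sided binomial on sign counts
after dropping ties (undefined if everything ties). Wilcoxon and
Mann-Whitney report an exact p where scipy can enumerate it (n ≤ 25, no
ties) alongside the tie-corrected normal approximation; the Wilcoxon Z uses
a 0.5 continuity correction, without which exact and asymptotic p diverge
by more than 0.02 at n = 15. Identical paired samples yield p = 1 with a
degenerate flag rather than an error. The τ-vs-frequency regression is OLS
with an F-test of zero slope on (1, n − 2) df, invariant to affine
rescaling of the frequency axis.

## What the generator does and does not show

Passing the recovery suite shows the estimators are correct for signals
with the generator's structure: stationary band-limited Gaussian noise,
stereotyped waveforms, Gaussian rate jitter, exponential potentiation.
Real recordings add nonstationary baselines, movement and stimulus
artifacts, CAP shape variability between and within preparations, and
occasional electrode drift — none of which the generator emulates. Results
on real data therefore depend on threshold choices (`threshold_k`,
refractory intervals, the call gap) that the synthetic tests cannot
validate; the defaults here are sensible starting points, not guarantees.

## Problem sizes and determinism

The recovery benchmarks use desk-scale problems chosen to make the checks
sharp: 30-pulse evoked series; 11 paired pre/post brains with one biphasic
call each (14 fast / 12 slow CAPs); ≥ 2000 click intervals for unimodal and
≥ 1000 per mode for bimodal rate models; 1 s LFP segments at 10 kHz (1 Hz
spectral resolution). All are regenerated at run time from the seed; the
demo writes byte-identical summaries for identical configurations.

## Known limitations

- Detection assumes one CAP per laryngeal burst (population events); no
  spike sorting, overlapping-unit resolution, or matched filtering.
- "Long-slow" calls can use double clicks as their repetition unit; both
  clicks of a doublet are kept as events, so doublet intervals appear as a
  fast lobe in the rate histogram rather than being collapsed.
- The bimodal rate model fits two free Gaussians, not a constrained
  mixture; on strongly unimodal data it returns near-identical components
  or a degenerate-component warning rather than a spurious second mode.
- `mean_psd` requires equal segment lengths by design; resampling spectra
  to a common grid is out of scope.
- Transection status is a labeled scenario, never inferred from the data.
- Pharmacological conditions exist only as generator scenario labels; no
  receptor-level modeling.
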