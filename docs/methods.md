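# Methods

## The system and the measurement problem

The pipeline quantifies how fast an insect compound eye converts light into
the electroretinogram (ERG), a field potential dominated by summed
photoreceptor currents, and how that speed changes with behavioural state
and eye temperature. Speed is expressed two ways: as a *latency* (a pure
time offset between stimulus and response) and as *filter kinetics* (the
time constant and damping of a linear transfer function). The two are
deliberately kept separate — warming the eye both shortens the latency and
shifts the frequency response upward, and the analysis must resolve each
independently.

## Signal model

The stimulus is band-limited Gaussian white noise: a 10 s Gaussian token
low-pass filtered with a nine-pole digital Butterworth (bilinear transform)
at a 250 Hz corner, which leaves the power spectrum flat (±1 dB) to about
220 Hz at the native 3 kHz rate. Intensity scaling maps the dimensionless
token onto a non-negative photon flux: the trace is standardised, scaled to
30 % relative contrast around the target mean, clipped at zero (a
negligible fraction at that contrast, logged when it occurs) and rescaled
so the mean is met exactly. Pulse stimulation uses rectangular 50 ms
pulses at 1 Hz.

The ERG is modelled, both for generation and for fitting, as a delayed,
sign-inverted second-order low-pass response

    H(f) = β / (1 + 2jωτζ − (ωτ)²),  ω = 2πf,

applied to the stimulus contrast, plus white recording noise and an
optional 150 Hz line artefact. Promoting the fitted filter to the forward
model is a deliberate design choice: it makes parameter recovery a
well-posed, falsifiable test of the whole estimation chain. The transfer
function (including the pure delay term e^{−jωd}) is applied exactly in
the frequency domain rather than through a discretised IIR filter, so the
generated data obey |H| at every resolved frequency without
bilinear-transform frequency warping; piecewise-constant parameter blocks
are filtered with 1 s context padding so FFT wrap-around never touches the
kept samples.

## Temperature structure

Two linear relations drive the temperature dependence:

* total latency: `latency(T) = 22.21 ms − 0.48 ms/°C · T`, with per-animal
  random intercepts and slopes; valid only over roughly 24–38 °C (the
  generator warns outside this range — the relation must saturate at
  higher temperatures);
* filter time constant: linear through the anchors (26.9 °C, 1.48 ms) and
  (31.9 °C, 1.14 ms).

The measured cross-correlation latency of a second-order response exceeds
the pure transduction delay by the filter's own lag, so the generator
calibrates: it measures the filter-only correlogram lag (or, for pulses,
the filter-only half-maximum lag) on a noiseless probe and sets
`delay = target latency − filter lag`. Cross-correlation latency then
tracks the latency–temperature relation by construction, and β and ζ stay
temperature-independent by default (heating-specific ζ/β medians are
available as explicit per-epoch parameters).

Session temperature follows a piecewise trajectory: baseline, a linear
ramp during the active epoch (walking default +2.3 °C; heating to a 37 °C
peak), and exponential recovery with a 120 s time constant, plus smoothed
measurement noise. Locomotion is positive only during walking epochs.

## Estimators and numerical choices

* **Cross-correlogram** — both segments demeaned, each lag normalised by
  the energies of the overlapping parts, so Cauchy–Schwarz bounds every
  value in [−1, 1] exactly. Latency is the minimum over positive lags
  (default search 0–30 ms) with parabolic three-point refinement; 3 kHz
  sampling (0.33 ms) is coarse next to the 0.1 ms effects of interest.
  An extremum on the search boundary raises a warning rather than a value
  silently clipped to the range.
* **Half-maximum latency** — per pulse, referenced to a 5 ms pre-onset
  baseline, thresholded at half of *that response's* maximum absolute
  amplitude within a 100 ms window (robust to slow amplitude drift),
  linearly interpolated, averaged over the segment's pulses. Missing
  crossings propagate as NaN; only an all-missing segment is an error.
* **Spectra** — resampling to 1 ms intervals uses a polyphase FIR
  (Kaiser β = 8, cutoff at 0.92 of the output Nyquist: a 400 Hz tone
  survives with < 5 % loss, a 600 Hz tone is attenuated > 90 %). Welch
  averaging with 512-point Hann segments at 50 % overlap is the default;
  plain disjoint rectangular segments are available. Coherence uses the
  averaged-spectra magnitude-squared form |⟨S_xy⟩|²/(⟨S_xx⟩⟨S_yy⟩) — the
  per-segment square would be identically 1. At least two segments are
  required.
* **Fit** — weighted least squares on gain magnitude with weights γ²(f),
  band 2–220 Hz (above the DC bin, inside the stimulus flatness limit),
  excluding 146–154 Hz around the line artefact. Positivity is enforced
  by optimising log(β, τ, ζ); the initial guess takes τ from the resonance
  peak (or the −3 dB point when over-damped), plus five seeded jittered
  restarts, because strongly resonant gains (ζ ≈ 0.15) create local
  minima. Noiseless model data are recovered to < 0.1 % across
  β ∈ [0.1, 10], τ ∈ [0.5, 5] ms, ζ ∈ [0.05, 1]. A log-magnitude residual
  option exists but magnitude weighting is the default.
* **Segments** — evaluation windows are 5 s: the last 5 s before activity,
  the window immediately *after* activity for real recordings (walking
  artefacts contaminate the ERG during locomotion), or the tail of the
  active epoch itself for artefact-free synthetic data, and a recovery
  window at least 300 s after activity ends (flagged unavailable on short
  recordings). Epochs can also be derived from the locomotion channel
  (speed above threshold sustained ≥ 2 s).
* **Statistics** — Wilcoxon signed-rank p-values are exact for n ≤ 25
  (they match full 2ⁿ sign-pattern enumeration) and normal-approximated
  above; three contrasts give the Bonferroni threshold 0.0167. The mixed
  model uses REML coefficients with ML likelihood-ratio comparisons and
  AIC selection; random structure is per-animal intercept + temperature
  slope, falling back to intercept-only on singular fits. Fixed-effect
  CIs come from a by-animal (cluster) bootstrap, 200 resamples by
  default. Post-hoc contrasts use Wald z statistics; small-sample
  degree-of-freedom corrections (Kenward–Roger/Satterthwaite) are not
  applied — at these cohort sizes and tolerances the difference is
  immaterial, and the treatment contrast is always reported from the
  +treatment model so a small offset stays quantified even when AIC
  prefers the simpler model.

## What the generator does and does not emulate

It reproduces the statistical structure the estimators rely on: the
stimulus spectrum, the linear transfer with realistic (β, τ, ζ), additive
noise at a broadband amplitude SNR of 2 (passband coherence comes out
somewhat above the ~0.9 typical of good recordings), the 150 Hz artefact,
temperature/locomotion covariates, per-animal heterogeneity with cohort
medians pinned exactly, and the adaptation model for the intensity series
(latency linear in log intensity, calibrated to a 1.4 ms span over the
14-fold range). It does **not** emulate walking artefacts, photoreceptor
nonlinearity (coherence loss is purely additive-noise), slow drift,
saturating temperature dependence, or thermoregulatory physiology — so
passing recovery tests demonstrates correctness of the estimation chain
on in-model data, not robustness to every pathology of real recordings.
One consequence worth noting: per-animal latency offsets are shared across
epochs, so even a 0.2 ms generating difference between the two sitting
conditions is perfectly paired and can reach significance, which real
measurement noise would usually mask.

## Problem sizes

Cohort experiments use the study-sized designs (12 walking, 22 heated,
16 pulse animals; 34 animals × 5 temperatures for the mixed model) with
35 s sitting/active epochs — long enough for ~18 Welch segments per 5 s
evaluation window and stable medians. The full validation run takes about
one minute on a single CPU; the per-session temperature channel is sampled
at 10 Hz and locomotion at 50 Hz to keep containers small.

## Known limitations

* The Welch/Hann estimator carries a small leakage bias (~1.5 %) at the
  sharp resonance peak of strongly under-damped gains; it is visible in
  the 2 % round-trip tolerance and negligible after coherence-weighted
  fitting (τ, ζ medians recover within 1–2 %).
* Coherence from few segments is biased upward; estimates from a 5 s
  window (18 segments) are adequate for weighting but not for absolute
  coherence statements.
* The latency–temperature relation and the τ anchors are linear
  interpolations; neither extrapolates sensibly far outside 24–38 °C.
* The mixed model's bootstrap CI is percentile-based over animals; with
  very few animals per group it can under-cover slightly (coverage is
  verified ≥ 90 % across simulated cohorts).
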