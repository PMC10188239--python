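# ergpipe

Latency and frequency-response analysis of insect electroretinograms (ERGs)
under Gaussian white-noise and pulse stimulation — built for the question of
how locomotion- and temperature-driven state changes speed up photoreceptor
responses in the bumblebee (*Bombus terrestris*) compound eye.

The package is organised as an analysis project: the library under
`src/ergpipe/` implements every computational step, the numbered scripts
under `analysis/` are thin narrative drivers that run the cohort-level
analyses and write their tables under `results/`, and
`scripts/acceptance.py` re-runs the validation experiments end to end.

## What it computes

**Latency.** Two estimators of the stimulus-to-ERG delay:

* *pulse half-maximum*: time from pulse onset to the first crossing of 50 %
  of that response's maximum amplitude (linearly interpolated between
  samples), averaged over the five pulses of a 5 s evaluation segment;
* *cross-correlation*: the ERG is inversely correlated with the light
  stimulus, so the lag of the **minimum** of the normalised cross-correlogram
  between photodiode and ERG is the latency (parabolic sub-sample
  refinement; values bounded in [−1, 1] by construction).

**Coherence and gain.** Both channels are resampled to 1 ms intervals and
split into 512-point segments (Hann window, 50 % overlap); from the
ensemble-averaged spectra,

    γ²(f) = |⟨S_xy⟩|² / (⟨S_xx⟩ ⟨S_yy⟩),      G(f) = ⟨S_xy⟩ / ⟨S_xx⟩.

**Filter fit.** The gain magnitude is fitted with a second-order low-pass

    H(f) = β / (1 + 2jωτζ − (ωτ)²),   ω = 2πf,

weighted by the coherence, over 2–220 Hz with a ±4 Hz band around the
150 Hz line artefact excluded. β is the amplitude, τ the time constant
(smaller τ → higher roll-off frequency → faster vision), ζ the damping
(ζ ≈ 0.15 gives the pronounced resonance of light-adapted photoreceptors).

**Statistics.** Paired Wilcoxon signed-rank tests across the
sitting/active/sitting conditions with Bonferroni correction
(α = 0.05/3 ≈ 0.0167), and a linear mixed-effects model of latency on eye
temperature (per-animal random intercepts and slopes, treatment fixed
effect, likelihood-ratio/AIC model selection, by-animal bootstrap CIs).

**Synthetic sessions.** Because the pipeline must be testable without raw
recordings, `ergpipe.synthetic` generates complete sessions — looped
band-limited noise stimulus (nine-pole Butterworth, 250 Hz corner), ERG as
a delayed, sign-inverted second-order low-pass response with recording
noise and optional 150 Hz artefact, temperature ramps (walking ≈ +2.3 °C,
heating to ≈ 37 °C) with exponential recovery, and a locomotion channel —
with per-animal random effects and exact cohort-median pinning so that
*parameter recovery* is well posed: cohorts generated with known condition
medians must hand those medians back through the full estimation chain.

## Worked example

```python
from ergpipe.experiments import noise_cohort_recovery

out = noise_cohort_recovery("walking", n_animals=12, seed=1)
print({k: round(v, 3) for k, v in out["median_tau_ms"].items()})
print({k: round(v, 3) for k, v in out["median_latency_ms"].items()})
```

prints

```
{'active': 1.25, 'before': 1.407}
{'active': 7.43, 'before': 8.99}
```

i.e. the 12-animal synthetic walking cohort was generated with
condition-median time constants 1.41 ms (sitting) and 1.25 ms (walking)
and cross-correlation latencies 9.0 / 7.4 ms, and the full pipeline —
segmentation, 1 ms resampling, Welch spectra, coherence-weighted fit,
correlogram minimum — recovers exactly those values: walking shortens the
latency by ~1.6 ms and shrinks τ, the signature of faster vision.

The cohort-level drivers run the same analyses with tables and figures:

```
python analysis/01_simulate_cohorts.py --seed 1     # HDF5 session containers
python analysis/02_pulse_latency.py    --seed 1     # half-max latency + Wilcoxon
python analysis/03_noise_latency_spectra.py --seed 1
python analysis/04_temperature_model.py --seed 1    # mixed-effects model
python analysis/05_intensity_series.py  --seed 1    # 14-fold intensity series
```

A small `ergpipe` CLI (`simulate` / `analyze` / `report`) wraps the same
library for ad-hoc use on directories of HDF5 sessions.

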