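"""Synthetic recording sessions with the statistical structure the analysis
assumes.

The generative ERG model is the same second-order low-pass that the
estimation stage fits: the ERG is a sign-inverted, delayed, resonant
low-pass response to the light stimulus, plus Gaussian recording noise and
an optional 150 Hz line artefact.  Temperature acts through two separate
knobs — the total stimulus-to-response latency follows a linear
latency–temperature relation (default: latency = 22.21 - 0.48 ms/degC),
and the filter time constant tau shrinks linearly with temperature between
two anchor points (1.48 ms at 26.9 degC, 1.14 ms at 31.9 degC).  The pure
transduction delay absorbs whatever part of the total latency the filter's
own group delay does not account for, so cross-correlation latency tracks
the latency–temperature relation by construction.

Sessions follow the walking/heating protocol: the animal sits, then walks
(or is heated), then sits again; visual stimulation (a looped 10 s
band-limited noise token, or a 1 Hz pulse train) is continuous throughout.
Eye temperature ramps up during the active epoch (default walking rise
2.3 degC; heating to a 37 degC peak) and decays exponentially afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import (Epoch, InvalidArgumentError, RangeWarning, Session,
                   TimeSeries, require)
from .filter_fit import model_response
from .latency import cross_correlate, pulse_latency_half_max, xcorr_latency
from .stimulus import (DEFAULT_RATE, NOISE_MEAN_INTENSITY, PULSE_INTENSITY,
                       INTENSITY_SERIES, StimulusSpec, butterworth_lowpass,
                       generate_pulse_train, generate_white_noise,
                       noise_token, scale_intensity)

__all__ = [
    "PhotoreceptorParams",
    "TemperatureModel",
    "ProtocolSpec",
    "CohortSpec",
    "second_order_response",
    "latency_from_temperature",
    "tau_from_temperature",
    "simulate_session",
    "simulate_cohort",
    "simulate_pulse_cohort",
    "simulate_intensity_series",
    "simulate_latency_measurements",
    "filter_xcorr_lag",
    "filter_halfmax_lag",
    "walking_protocol",
    "heating_protocol",
    "null_protocol",
    "WALKING_EPOCH_PARAMS",
    "HEATING_EPOCH_PARAMS",
    "WALKING_LATENCY_MS",
    "PULSE_LATENCY_MS",
    "adaptation_latency",
]


# ---------------------------------------------------------------------------
# parameters and defaults

@dataclass(frozen=True)
class PhotoreceptorParams:
    """Forward-model parameters for one animal/epoch.

    ``beta`` is the gain amplitude (ERG units per unit drive), ``tau`` the
    filter time constant in ms, ``zeta`` the dimensionless damping,
    ``delay`` the pure transduction latency in ms, ``polarity`` the sign of
    the ERG relative to the stimulus (-1: light-on drives the ERG
    negative), ``noise_sd`` the additive recording-noise s.d. in ERG units
    and ``artefact_150hz_amp`` the amplitude of an optional 150 Hz line
    artefact.
    """

    beta: float = 1.0
    tau: float = 1.41
    zeta: float = 0.150
    delay: float = 8.0
    polarity: int = -1
    noise_sd: float = 0.0
    artefact_150hz_amp: float = 0.0

    def __post_init__(self) -> None:
        require(self.tau > 0 and self.zeta > 0 and self.beta > 0, "beta, tau, zeta must be positive")
        require(self.delay >= 0, "delay must be non-negative")
        require(self.polarity in (-1, 1), "polarity must be +-1")


@dataclass(frozen=True)
class TemperatureModel:
    """Linear latency- and tau-versus-temperature model.

    ``slope``/``intercept`` give total latency in ms as a function of eye
    temperature in degC (negative slope: warmer eyes respond faster).  The
    filter time constant is interpolated linearly through ``tau_ref``
    with slope ``tau_slope`` (ms per degC).
    """

    slope: float = -0.48          # ms per degC
    intercept: float = 22.21      # ms at 0 degC
    tau_slope: float = (1.14 - 1.48) / (31.9 - 26.9)  # ms per degC
    tau_ref: tuple[float, float] = (26.9, 1.48)       # (degC, ms)
    supported_range: tuple[float, float] = (24.0, 38.0)


#: Condition-median filter parameters (beta, tau ms, zeta) for the walking
#: protocol; beta is condition-independent by default.
WALKING_EPOCH_PARAMS: dict[str, tuple[float, float, float]] = {
    "before": (1.0, 1.41, 0.150),
    "active": (1.0, 1.25, 0.146),
    "after": (1.0, 1.39, 0.148),
}

#: Condition-median filter parameters for the heating protocol (damping
#: rises under heating, unlike walking).
HEATING_EPOCH_PARAMS: dict[str, tuple[float, float, float]] = {
    "before": (1.0, 1.48, 0.165),
    "active": (1.0, 1.14, 0.184),
    "after": (1.0, 1.45, 0.148),
}

#: Cohort-median cross-correlation latencies (ms) under noise stimulation.
WALKING_LATENCY_MS: dict[str, float] = {"before": 9.0, "active": 7.4, "after": 9.0}

#: Cohort-median half-maximum pulse latencies (ms).
PULSE_LATENCY_MS: dict[str, float] = {"before": 10.3, "active": 8.7, "after": 10.1}


@dataclass(frozen=True)
class ProtocolSpec:
    """Epoch timing and temperature trajectory of one protocol run."""

    kind: str = "walking"          # walking | heating | null | intensity
    before_s: float = 60.0
    active_s: float = 60.0
    after_s: float = 320.0         # >= 300 s so a recovery segment exists
    temp_baseline: float = 27.6    # degC at rest
    temp_rise: float = 2.3         # degC rise during walking
    temp_peak: float = 37.0        # degC target for heating
    decay_tau_s: float = 120.0     # post-active exponential decay
    temp_noise_sd: float = 0.05

    def durations(self) -> tuple[float, float, float]:
        return self.before_s, self.active_s, self.after_s


def walking_protocol(**changes) -> ProtocolSpec:
    return replace(ProtocolSpec(kind="walking"), **changes)


def heating_protocol(**changes) -> ProtocolSpec:
    return replace(ProtocolSpec(kind="heating", temp_baseline=26.9), **changes)


def null_protocol(**changes) -> ProtocolSpec:
    """Sitting throughout; no temperature change (control)."""
    return replace(ProtocolSpec(kind="null", temp_rise=0.0), **changes)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of animals run through one protocol.

    Per-animal random effects (latency intercept s.d. in ms, temperature
    slope s.d. in ms/degC) mirror between-individual differences in average
    latency and temperature response.  ``epoch_params`` pins the filter
    parameters per condition (the parameter-recovery configuration);
    without it tau/delay are derived from the temperature trace.
    ``param_jitter`` gives relative multiplicative spreads for
    (tau, zeta, beta) across animals, re-centred so cohort medians equal
    the configured values exactly.
    """

    n_animals: int = 12
    protocol: ProtocolSpec = field(default_factory=walking_protocol)
    latency_intercept_sd: float = 0.8
    temp_slope_sd: float = 0.05
    temp_rise_mean: float = 2.3
    temp_rise_sd: float = 0.8
    seed: int = 0
    epoch_params: dict[str, tuple[float, float, float]] | None = None
    latency_medians: dict[str, float] | None = None
    param_jitter: tuple[float, float, float] = (0.05, 0.04, 0.20)
    snr: float = 2.0
    artefact_rel_amp: float = 0.05
    temperature_model: TemperatureModel = field(default_factory=TemperatureModel)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    heated_offset_ms: float = 0.0   # optional slowing of the heated group

    def __post_init__(self) -> None:
        require(self.n_animals >= 1, "n_animals must be >= 1")
        require(self.latency_intercept_sd >= 0 and self.temp_slope_sd >= 0,
                "random-effect sds must be >= 0")


# ---------------------------------------------------------------------------
# forward model

def _apply_transfer(x: np.ndarray, rate: float, beta: float, tau_ms: float,
                    zeta: float, delay_ms: float, polarity: int) -> np.ndarray:
    """Exact frequency-domain application of polarity * H(f) * e^{-jw d}."""
    n = x.size
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    H = model_response(f, beta, tau_ms, zeta) * np.exp(-2j * np.pi * f * delay_ms / 1000.0)
    return polarity * np.fft.irfft(X * H, n)


def second_order_response(stimulus: TimeSeries, params: PhotoreceptorParams,
                          seed: int | None = None) -> TimeSeries:
    """Forward ERG model: delayed, sign-inverted second-order low-pass
    response to the stimulus, plus recording noise and optional 150 Hz
    artefact.

    The transfer function is applied exactly in the frequency domain, so
    with zero noise the stimulus-to-output magnitude equals |H(f)| at every
    resolved frequency.
    """
    fn = 1.0 / (2.0 * math.pi * params.tau / 1000.0)
    if fn >= stimulus.rate / 2.0:
        raise InvalidArgumentError(
            f"tau={params.tau} ms places the natural frequency {fn:.0f} Hz at or "
            f"above Nyquist ({stimulus.rate / 2:.0f} Hz)"
        )
    y = _apply_transfer(stimulus.samples, stimulus.rate, params.beta, params.tau,
                        params.zeta, params.delay, params.polarity)
    if params.noise_sd > 0 or params.artefact_150hz_amp > 0:
        rng = np.random.default_rng(seed)
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, y.size)
        if params.artefact_150hz_amp > 0:
            phase = rng.uniform(0, 2 * math.pi)
            y = y + params.artefact_150hz_amp * np.sin(
                2 * math.pi * 150.0 * stimulus.times + phase)
    return TimeSeries(y, stimulus.rate, stimulus.t0, "mV")


def latency_from_temperature(T: float, model: TemperatureModel = TemperatureModel(),
                             animal_offsets: tuple[float, float] = (0.0, 0.0)) -> float:
    """Total stimulus-to-ERG latency (ms) at eye temperature ``T`` (degC).

    ``animal_offsets`` are per-animal (intercept, slope) deviations.  A
    temperature outside the supported range raises a :class:`RangeWarning`
    (the linear relation holds only over a limited range).
    """
    lo, hi = model.supported_range
    if not (lo <= T <= hi):
        warnings.warn(
            f"temperature {T} degC outside supported range [{lo}, {hi}]",
            RangeWarning,
        )
    b0, b1 = animal_offsets
    return model.intercept + b0 + (model.slope + b1) * T


def tau_from_temperature(T: float, model: TemperatureModel = TemperatureModel()) -> float:
    """Filter time constant (ms) at eye temperature ``T``, interpolated
    linearly through the model's anchor point."""
    T0, tau0 = model.tau_ref
    tau = tau0 + model.tau_slope * (T - T0)
    if tau <= 0:
        raise InvalidArgumentError(f"tau({T} degC) = {tau:.3f} ms is non-positive")
    return tau


# ---------------------------------------------------------------------------
# latency calibration of the forward model

def _probe_stimulus(rate: float) -> TimeSeries:
    raw = generate_white_noise(5.0, rate, seed=987654321)
    return butterworth_lowpass(raw, 250.0, 9)


@lru_cache(maxsize=256)
def _filter_xcorr_lag_cached(tau_r: float, zeta_r: float, rate: float) -> float:
    stim = _probe_stimulus(rate)
    p = PhotoreceptorParams(beta=1.0, tau=tau_r, zeta=zeta_r, delay=0.0)
    erg = second_order_response(stim, p)
    c = cross_correlate(stim, erg, max_lag_ms=15.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xcorr_latency(c, search_range_ms=(-15.0, 15.0))


def filter_xcorr_lag(tau_ms: float, zeta: float, rate: float = DEFAULT_RATE) -> float:
    """Cross-correlation lag (ms) contributed by the filter itself, measured
    on a noiseless band-limited probe.  Used to split a target total latency
    into pure delay + filter contribution."""
    return _filter_xcorr_lag_cached(round(tau_ms, 3), round(zeta, 3), rate)


@lru_cache(maxsize=256)
def _filter_halfmax_lag_cached(tau_r: float, zeta_r: float, rate: float,
                               pulse_width_ms: float) -> float:
    train, onsets = generate_pulse_train(1.0, rate, pulse_width_ms, 1.0, 1.0)
    p = PhotoreceptorParams(beta=1.0, tau=tau_r, zeta=zeta_r, delay=0.0)
    erg = second_order_response(train, p)
    return pulse_latency_half_max(erg, onsets)


def filter_halfmax_lag(tau_ms: float, zeta: float, rate: float = DEFAULT_RATE,
                       pulse_width_ms: float = 50.0) -> float:
    """Half-maximum latency (ms) of the noiseless filter response to a
    rectangular pulse, with zero pure delay."""
    return _filter_halfmax_lag_cached(round(tau_ms, 3), round(zeta, 3), rate,
                                      pulse_width_ms)


# ---------------------------------------------------------------------------
# session synthesis

def _temperature_trace(protocol: ProtocolSpec, rise: float, rng: np.random.Generator,
                       rate: float = 10.0) -> TimeSeries:
    b, a, f = protocol.durations()
    n = int(round((b + a + f) * rate))
    t = np.arange(n) / rate
    T = np.full(n, protocol.temp_baseline)
    in_active = (t >= b) & (t < b + a)
    T[in_active] = protocol.temp_baseline + rise * (t[in_active] - b) / a
    after = t >= b + a
    T[after] = protocol.temp_baseline + rise * np.exp(-(t[after] - b - a) / protocol.decay_tau_s)
    if protocol.temp_noise_sd > 0:
        noise = rng.normal(0.0, protocol.temp_noise_sd, n)
        kernel = np.ones(int(rate)) / rate  # 1 s smoothing
        T = T + np.convolve(noise, kernel, mode="same")
    return TimeSeries(T, rate, 0.0, "degC")


def _motion_trace(protocol: ProtocolSpec, rng: np.random.Generator,
                  rate: float = 50.0) -> TimeSeries:
    b, a, f = protocol.durations()
    n = int(round((b + a + f) * rate))
    v = np.zeros(n)
    if protocol.kind == "walking":
        i0, i1 = int(b * rate), int((b + a) * rate)
        raw = rng.normal(3.0, 1.0, i1 - i0)
        kernel = np.ones(int(rate // 2)) / (rate // 2)
        v[i0:i1] = np.clip(np.convolve(raw, kernel, mode="same") + 2.0, 0.5, None)
    return TimeSeries(v, rate, 0.0, "cm/s")


def _looped_noise_stimulus(spec: StimulusSpec, total_s: float, rate: float) -> TimeSeries:
    token = noise_token(spec, rate)
    n = int(round(total_s * rate))
    reps = int(np.ceil(n / len(token)))
    return TimeSeries(np.tile(token.samples, reps)[:n], rate, 0.0, token.units)


def _filtered_piecewise(drive: np.ndarray, rate: float,
                        blocks: list[tuple[int, int, float, float, float, float]],
                        polarity: int, context_s: float = 1.0) -> np.ndarray:
    """Apply per-block transfer functions with context padding so FFT
    wrap-around never touches the kept samples.

    ``blocks`` rows are (i0, i1, beta, tau_ms, zeta, delay_ms).
    """
    out = np.empty_like(drive)
    ctx = int(round(context_s * rate))
    n = drive.size
    for i0, i1, beta, tau, zeta, delay in blocks:
        j0, j1 = max(0, i0 - ctx), min(n, i1 + ctx)
        seg = _apply_transfer(drive[j0:j1], rate, beta, tau, zeta, delay, polarity)
        out[i0:i1] = seg[i0 - j0:i1 - j0]
    return out


@dataclass(frozen=True)
class MemberParams:
    """Per-animal generative settings produced by the cohort sampler."""

    animal_id: str = "a00"
    epoch_params: dict[str, tuple[float, float, float]] | None = None
    latency_targets: dict[str, float] | None = None
    latency_offsets: tuple[float, float] = (0.0, 0.0)
    temp_rise: float = 2.3
    snr: float = 2.0
    artefact_rel_amp: float = 0.0
    temperature_model: TemperatureModel = field(default_factory=TemperatureModel)


def simulate_session(spec: StimulusSpec, member: MemberParams,
                     protocol: ProtocolSpec, seed: int,
                     rate: float = DEFAULT_RATE) -> Session:
    """Generate one complete synthetic session (stimulus, ERG, temperature,
    motion, epochs).

    With ``member.epoch_params`` set, the filter parameters are held at the
    given (beta, tau, zeta) per condition epoch and the pure delay is
    calibrated per epoch so the cross-correlation latency equals the
    member's epoch latency target.  Otherwise tau and delay are derived
    block-wise (5 s blocks) from the temperature trace through the
    latency- and tau-versus-temperature models.
    """
    if protocol.kind not in ("walking", "heating", "null", "intensity"):
        raise InvalidArgumentError(f"unknown protocol kind {protocol.kind!r}")
    rng = np.random.default_rng(seed)
    b, a, f = protocol.durations()
    total = b + a + f
    epochs = [Epoch("before", 0.0, b), Epoch("active", b, b + a),
              Epoch("after", b + a, total)]

    if protocol.kind == "heating":
        rise = protocol.temp_peak - protocol.temp_baseline
    elif protocol.kind in ("null", "intensity"):
        rise = 0.0
    else:
        rise = member.temp_rise
    temperature = _temperature_trace(protocol, rise, rng)
    motion = _motion_trace(protocol, rng)

    if spec.kind == "pulse":
        stim, onsets = generate_pulse_train(total, rate, spec.pulse_width,
                                            spec.pulse_rate, spec.mean_intensity)
        meta_onsets = onsets
    else:
        stim = _looped_noise_stimulus(spec, total, rate)
        meta_onsets = []

    mean_i = float(np.mean(stim.samples)) or 1.0
    drive = (stim.samples - mean_i) / mean_i

    # assemble constant-parameter blocks
    blocks: list[tuple[int, int, float, float, float, float]] = []
    model = member.temperature_model
    if member.epoch_params is not None:
        targets = member.latency_targets or {}
        for ep in epochs:
            beta, tau, zeta = member.epoch_params[ep.label]
            if spec.kind == "pulse":
                lag0 = filter_halfmax_lag(tau, zeta, rate, spec.pulse_width)
            else:
                lag0 = filter_xcorr_lag(tau, zeta, rate)
            target = targets.get(ep.label)
            if target is None:
                Tm = float(np.mean(temperature.crop(ep.start, ep.end).samples))
                target = latency_from_temperature(Tm, model, member.latency_offsets)
            delay = max(target - lag0, 0.05)
            i0, i1 = int(round(ep.start * rate)), int(round(ep.end * rate))
            blocks.append((i0, i1, beta, tau, zeta, delay))
    else:
        block_s = 5.0
        n_blocks = int(np.ceil(total / block_s))
        beta0, zeta0 = 1.0, 0.150
        for kblk in range(n_blocks):
            t0b, t1b = kblk * block_s, min((kblk + 1) * block_s, total)
            Tm = float(np.mean(temperature.crop(t0b, t1b).samples))
            tau = tau_from_temperature(Tm, model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RangeWarning)
                target = latency_from_temperature(Tm, model, member.latency_offsets)
            if spec.kind == "pulse":
                lag0 = filter_halfmax_lag(tau, zeta0, rate, spec.pulse_width)
            else:
                lag0 = filter_xcorr_lag(tau, zeta0, rate)
            delay = max(target - lag0, 0.05)
            i0, i1 = int(round(t0b * rate)), int(round(t1b * rate))
            blocks.append((i0, i1, beta0, tau, zeta0, delay))

    clean = _filtered_piecewise(drive, rate, blocks, polarity=-1)
    rms = float(np.std(clean)) or 1.0
    noise_sd = rms / member.snr if member.snr > 0 else 0.0
    erg = clean.copy()
    if noise_sd > 0:
        erg += rng.normal(0.0, noise_sd, erg.size)
    if member.artefact_rel_amp > 0:
        phase = rng.uniform(0, 2 * math.pi)
        erg += member.artefact_rel_amp * rms * np.sin(
            2 * math.pi * 150.0 * np.arange(erg.size) / rate + phase)

    return Session(
        animal_id=member.animal_id,
        channels={
            "stimulus": stim,
            "erg": TimeSeries(erg, rate, 0.0, "mV"),
            "temperature": temperature,
            "motion": motion,
        },
        epochs=epochs,
        protocol=protocol.kind,
        intensity=spec.mean_intensity,
        meta={
            "seed": seed,
            "pulse_onsets": meta_onsets,
            "treatment": {"walking": "walking", "heating": "heated"}.get(protocol.kind, ""),
            "generating_blocks": blocks,
        },
    )


def _centred_lognormal(rng: np.random.Generator, n: int, rel_sd: float) -> np.ndarray:
    """Multiplicative jitter factors with sample median exactly 1."""
    if rel_sd <= 0 or n == 1:
        return np.ones(n)
    g = np.exp(rng.normal(0.0, rel_sd, n))
    return g / np.median(g)


def _centred_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Additive offsets with sample median exactly 0."""
    if sd <= 0 or n == 1:
        return np.zeros(n)
    z = rng.normal(0.0, sd, n)
    return z - np.median(z)


def _sample_members(spec: CohortSpec, latency_medians: dict[str, float] | None
                    ) -> list[MemberParams]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_animals
    tau_j = _centred_lognormal(rng, n, spec.param_jitter[0])
    zeta_j = _centred_lognormal(rng, n, spec.param_jitter[1])
    beta_j = _centred_lognormal(rng, n, spec.param_jitter[2])
    lat_off = _centred_normal(rng, n, spec.latency_intercept_sd)
    slope_off = rng.normal(0.0, spec.temp_slope_sd, n)
    rises = np.clip(rng.normal(spec.temp_rise_mean, spec.temp_rise_sd, n), 0.3, None)
    members = []
    for i in range(n):
        ep = None
        targets = None
        if spec.epoch_params is not None:
            ep = {lbl: (beta * beta_j[i], tau * tau_j[i], zeta * zeta_j[i])
                  for lbl, (beta, tau, zeta) in spec.epoch_params.items()}
        if latency_medians is not None:
            targets = {lbl: med + lat_off[i] + spec.heated_offset_ms
                       for lbl, med in latency_medians.items()}
        members.append(MemberParams(
            animal_id=f"a{i:02d}", epoch_params=ep, latency_targets=targets,
            latency_offsets=(lat_off[i], slope_off[i]), temp_rise=float(rises[i]),
            snr=spec.snr, artefact_rel_amp=spec.artefact_rel_amp,
            temperature_model=spec.temperature_model,
        ))
    return members


def simulate_cohort(spec: CohortSpec) -> list[Session]:
    """One session per animal; per-animal random effects are drawn once and
    the whole cohort is reproducible from ``spec.seed``."""
    members = _sample_members(spec, spec.latency_medians)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_animals) % (2**31)
    return [simulate_session(spec.stimulus, m, spec.protocol, int(s))
            for m, s in zip(members, seeds)]


def iter_cohort(spec: CohortSpec):
    """Lazily yield the cohort's sessions one at a time (memory-friendly)."""
    members = _sample_members(spec, spec.latency_medians)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_animals) % (2**31)
    for m, s in zip(members, seeds):
        yield simulate_session(spec.stimulus, m, spec.protocol, int(s))


def simulate_pulse_cohort(n_animals: int = 16, seed: int = 0,
                          latency_medians: dict[str, float] | None = None,
                          latency_sd: float = 0.8, snr: float = 10.0,
                          protocol: ProtocolSpec | None = None) -> list[Session]:
    """Pulse-protocol cohort: 50 ms pulses at 1 Hz, per-animal generating
    half-maximum latencies spread around the condition medians with the
    cohort median pinned exactly at the median value."""
    latency_medians = latency_medians or PULSE_LATENCY_MS
    protocol = protocol or walking_protocol(before_s=6.0, active_s=6.0, after_s=6.0)
    pulse_spec = StimulusSpec(kind="pulse", duration=protocol.before_s,
                              mean_intensity=PULSE_INTENSITY)
    spec = CohortSpec(
        n_animals=n_animals, protocol=protocol, seed=seed,
        latency_intercept_sd=latency_sd,
        epoch_params=WALKING_EPOCH_PARAMS, latency_medians=latency_medians,
        snr=snr, artefact_rel_amp=0.0, stimulus=pulse_spec,
    )
    return simulate_cohort(spec)


def adaptation_latency(intensity: float, reference_latency: float = 9.0,
                       reference_intensity: float = NOISE_MEAN_INTENSITY,
                       ms_per_decade: float | None = None) -> float:
    """Latency under light adaptation: linear in log10 intensity, calibrated
    so the default highest-vs-lowest difference over the standard intensity
    series is 1.4 ms."""
    if ms_per_decade is None:
        span = math.log10(INTENSITY_SERIES[-1] / INTENSITY_SERIES[0])
        ms_per_decade = 1.4 / span
    return reference_latency - ms_per_decade * math.log10(intensity / reference_intensity)


def simulate_intensity_series(intensities=INTENSITY_SERIES, n_animals: int = 17,
                              seed: int = 0, duration_s: float = 12.0,
                              snr: float = 2.0, latency_sd: float = 0.6
                              ) -> list[Session]:
    """Sitting animals stimulated at each of the given mean intensities
    (ascending); latency decreases with log intensity via the adaptation
    model.  Returns one Session per animal and intensity."""
    intensities = list(intensities)
    require(all(i > 0 for i in intensities), "intensities must be positive")
    require(all(b > a for a, b in zip(intensities, intensities[1:])) or len(intensities) == 1,
            "intensities must be ascending")
    rng = np.random.default_rng(seed)
    lat_off = _centred_normal(rng, n_animals, latency_sd)
    seeds = np.random.SeedSequence(seed).generate_state(n_animals * len(intensities)) % (2**31)
    third = duration_s / 3.0
    protocol = null_protocol(before_s=third, active_s=third, after_s=third,
                             temp_baseline=27.0)
    sessions = []
    k = 0
    for i in range(n_animals):
        for intensity in intensities:
            target = adaptation_latency(intensity) + lat_off[i]
            member = MemberParams(
                animal_id=f"a{i:02d}",
                epoch_params={lbl: WALKING_EPOCH_PARAMS["before"] for lbl in
                              ("before", "active", "after")},
                latency_targets={lbl: target for lbl in ("before", "active", "after")},
                snr=snr,
            )
            stim_spec = StimulusSpec(kind="noise", duration=10.0,
                                     mean_intensity=intensity, seed=seed)
            sessions.append(simulate_session(stim_spec, member, protocol, int(seeds[k])))
            k += 1
    return sessions


def simulate_latency_measurements(n_walking: int = 12, n_heated: int = 22,
                                  n_temps: int = 5,
                                  model: TemperatureModel = TemperatureModel(),
                                  heated_offset_ms: float = 0.177,
                                  intercept_sd: float = 0.5, slope_sd: float = 0.05,
                                  noise_sd: float = 0.15, seed: int = 0) -> pd.DataFrame:
    """Latency-versus-temperature measurement table for the mixed-model
    analysis: each animal contributes ``n_temps`` evenly spaced eye
    temperatures over its own observed range, with per-animal random
    intercepts and temperature slopes and measurement noise.

    Walking animals span their baseline plus a ~2.3 degC rise; heated
    animals a ~5 degC rise.  The heated group is ``heated_offset_ms`` ms
    slower on average.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, rise_mu, rise_sd in (("walking", n_walking, 2.3, 0.8),
                                       ("heated", n_heated, 5.0, 1.0)):
        for i in range(n):
            base = rng.normal(27.0, 1.0)
            rise = max(rng.normal(rise_mu, rise_sd), 1.0)
            b0 = rng.normal(0.0, intercept_sd)
            b1 = rng.normal(0.0, slope_sd)
            temps = np.linspace(base, base + rise, n_temps)
            for T in temps:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RangeWarning)
                    lat = latency_from_temperature(float(T), model, (b0, b1))
                lat += (heated_offset_ms if group == "heated" else 0.0)
                lat += rng.normal(0.0, noise_sd)
                rows.append({"animal": f"{group[0]}{i:02d}", "treatment": group,
                             "temperature": float(T), "latency": float(lat)})
    return pd.DataFrame(rows)
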