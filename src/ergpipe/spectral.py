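"""Spectral estimation: auto-/cross-spectra, linear coherence and gain.

The estimator follows the classical ensemble-averaged recipe: both channels
are resampled to 1 ms intervals, split into 512-point segments (Hann window,
50 % overlap by default), FFT'd, and averaged.  From the averaged spectra,

    coherence  gamma^2(f) = |<Sxy>|^2 / (<Sxx> <Syy>)
    gain       G(f)       = <Sxy> / <Sxx>

Coherence is 1 at a frequency where the stimulus-to-ERG relationship is
linear and noise-free, and drops towards 0 with added noise or
nonlinearity; by Cauchy-Schwarz the averaged-spectra estimator is bounded in
[0, 1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EstimationError, InvalidArgumentError, TimeSeries, require

__all__ = [
    "SpectralEstimate",
    "resample_uniform",
    "estimate_spectra",
    "gain_magnitude",
    "DEFAULT_SEGMENT_LEN",
    "DEFAULT_RESAMPLE_MS",
]

#: FFT segment length (samples) for ensemble averaging.
DEFAULT_SEGMENT_LEN = 512

#: Standard resampling interval (ms) before spectral estimation.
DEFAULT_RESAMPLE_MS = 1.0


@dataclass
class SpectralEstimate:
    """Averaged spectra between an input (stimulus) and output (ERG) channel."""

    freqs: np.ndarray          # Hz, 0 .. Nyquist
    Sxx: np.ndarray            # input auto-spectrum (real, >= 0)
    Syy: np.ndarray            # output auto-spectrum (real, >= 0)
    Sxy: np.ndarray            # cross-spectrum (complex)
    n_segments: int
    rate: float

    def __post_init__(self) -> None:
        assert np.all(self.Sxx >= 0) and np.all(self.Syy >= 0)
        coh = self.coherence
        assert np.all((coh >= 0) & (coh <= 1.0 + 1e-12))

    @property
    def gain(self) -> np.ndarray:
        """Complex frequency response G(f) = <Sxy>/<Sxx>; NaN where Sxx = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(self.Sxx > 0, self.Sxy / np.where(self.Sxx > 0, self.Sxx, 1.0),
                         np.nan + 0j)
        return g

    @property
    def coherence(self) -> np.ndarray:
        """Magnitude-squared coherence gamma^2(f) in [0, 1]; 0 where undefined."""
        denom = self.Sxx * self.Syy
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.where(denom > 0, np.abs(self.Sxy) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(coh, 0.0, 1.0)


def resample_uniform(ts: TimeSeries, interval_ms: float = DEFAULT_RESAMPLE_MS) -> TimeSeries:
    """Anti-aliased resampling to a coarser uniform grid.

    ``interval_ms`` must be at least the native sample interval (this is a
    decimator, not an interpolator).  Rational rate ratios are handled with a
    polyphase FIR low-pass designed well inside the output Nyquist.
    """
    target_rate = 1000.0 / interval_ms
    if target_rate > ts.rate * (1 + 1e-9):
        raise InvalidArgumentError(
            f"upsampling requested: target {target_rate} Hz > native {ts.rate} Hz"
        )
    if abs(target_rate - ts.rate) <= 1e-9 * ts.rate:
        return ts
    frac = Fraction(target_rate / ts.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # sharp FIR keeps tones below ~0.9 Nyquist intact and kills aliases
    cutoff = 0.92 / down
    ntaps = 2 * 40 * down + 1
    h = signal.firwin(ntaps, cutoff, window=("kaiser", 8.0)) * up
    y = signal.resample_poly(ts.samples, up, down, window=h)
    return TimeSeries(y, target_rate, ts.t0, ts.units)


def estimate_spectra(x: TimeSeries, y: TimeSeries,
                     segment_len: int = DEFAULT_SEGMENT_LEN,
                     window: str = "hann", overlap: float = 0.5) -> SpectralEstimate:
    """Ensemble-averaged spectra between input ``x`` and output ``y``.

    Welch averaging with the given window and fractional ``overlap``
    (set ``window="boxcar", overlap=0`` for plain disjoint segments).
    Requires at least two segments — coherence is undefined from one.
    """
    require(abs(x.rate - y.rate) < 1e-9, "x and y must share a sampling rate")
    n = min(len(x), len(y))
    require(segment_len >= 8, "segment_len too short")
    noverlap = int(round(segment_len * overlap))
    step = segment_len - noverlap
    n_segments = 0 if n < segment_len else 1 + (n - segment_len) // step
    if n_segments < 2:
        raise EstimationError(
            f"need >= 2 spectral segments, have {n_segments} "
            f"({n} samples, segment_len={segment_len})"
        )
    xs, ys = x.samples[:n], y.samples[:n]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise EstimationError("zero-variance segment: spectra undefined")
    kw = dict(fs=x.rate, window=window, nperseg=segment_len, noverlap=noverlap,
              detrend="constant")
    freqs, Sxx = signal.welch(xs, **kw)
    _, Syy = signal.welch(ys, **kw)
    _, Sxy = signal.csd(xs, ys, **kw)
    return SpectralEstimate(freqs=freqs, Sxx=Sxx, Syy=Syy, Sxy=Sxy,
                            n_segments=int(n_segments), rate=x.rate)


def gain_magnitude(est: SpectralEstimate, drop_dc: bool = True
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Gain magnitude |G(f)| per frequency.

    Returns ``(freqs, |G|)``; bins with zero input power are NaN, and the DC
    bin is dropped by default (downstream fitting starts above DC).
    """
    g = np.abs(est.gain)
    freqs = est.freqs
    if drop_dc:
        freqs, g = freqs[1:], g[1:]
    return freqs, g
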