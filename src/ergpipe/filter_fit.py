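"""Second-order low-pass filter model of the photoreceptor frequency
response, and its coherence-weighted fit to measured gain curves.

The model is

    H(f) = beta / (1 + 2j*w*tau*zeta - (w*tau)^2),   w = 2*pi*f

with amplitude ``beta``, time constant ``tau`` and damping ``zeta``.  For
zeta < 1/sqrt(2) the magnitude has a resonance peak at
f_peak = sqrt(1 - 2*zeta^2) / (2*pi*tau).  Fitting minimises the
coherence-weighted squared residual of the gain magnitude; positivity of all
three parameters is enforced by optimising in log space, and a deterministic
multistart guards against the local minima created by strongly resonant
gains (zeta around 0.15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import EstimationError, InvalidArgumentError, require

__all__ = [
    "FilterFitResult",
    "model_gain",
    "model_response",
    "peak_frequency",
    "fit_gain",
    "normalize_beta",
    "DEFAULT_FIT_RANGE",
    "ARTEFACT_BAND",
]

#: Default frequency band used for fitting (Hz): above the DC bin, below the
#: flat-spectrum limit of the noise stimulus.
DEFAULT_FIT_RANGE = (2.0, 220.0)

#: Mains-artefact exclusion band (Hz), +-4 Hz around 150 Hz.
ARTEFACT_BAND = (146.0, 154.0)


@dataclass
class FilterFitResult:
    """Fitted second-order low-pass parameters for one gain curve."""

    beta: float
    tau: float  # ms
    zeta: float
    weighted_rss: float
    n_freqs: int
    converged: bool
    freq_range: tuple[float, float]
    n_starts: int = 0

    def __post_init__(self) -> None:
        if self.converged:
            assert self.beta > 0 and self.tau > 0 and self.zeta > 0


def model_response(f, beta: float, tau_ms: float, zeta: float) -> np.ndarray:
    """Complex transfer function H(f) at frequencies ``f`` (Hz), tau in ms."""
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    wt = w * (tau_ms / 1000.0)
    return beta / (1.0 + 2j * wt * zeta - wt**2)


def model_gain(f, beta: float, tau_ms: float, zeta: float) -> np.ndarray:
    """Gain magnitude |H(f)| = beta / sqrt((1-(wt)^2)^2 + (2*wt*zeta)^2)."""
    wt = 2.0 * np.pi * np.asarray(f, dtype=float) * (tau_ms / 1000.0)
    return beta / np.sqrt((1.0 - wt**2) ** 2 + (2.0 * wt * zeta) ** 2)


def peak_frequency(tau_ms: float, zeta: float) -> float:
    """Resonance-peak frequency in Hz, or 0.0 if the response is monotone
    (zeta >= 1/sqrt(2))."""
    if zeta >= 1.0 / np.sqrt(2.0):
        return 0.0
    return np.sqrt(1.0 - 2.0 * zeta**2) / (2.0 * np.pi * tau_ms / 1000.0)


def _initial_guess(freqs: np.ndarray, gain: np.ndarray) -> tuple[float, float, float]:
    beta0 = float(gain[0])
    i_pk = int(np.argmax(gain))
    if 0 < i_pk < len(gain) - 1 and gain[i_pk] > 1.2 * beta0:
        # interior resonance peak: tau from the peak frequency
        tau0 = 1000.0 / (2.0 * np.pi * freqs[i_pk])
        zeta0 = 0.2
    else:
        # monotone roll-off: tau from the -3 dB point
        below = np.nonzero(gain < beta0 / np.sqrt(2.0))[0]
        f3 = freqs[below[0]] if below.size else freqs[-1]
        tau0 = 1000.0 / (2.0 * np.pi * f3)
        zeta0 = 0.7
    return max(beta0, 1e-12), tau0, zeta0


def fit_gain(freqs, gain_mag, coherence_weights=None,
             freq_range: tuple[float, float] = DEFAULT_FIT_RANGE,
             exclude_band: tuple[float, float] | None = ARTEFACT_BAND,
             n_restarts: int = 5, seed: int = 0,
             log_magnitude: bool = False) -> FilterFitResult:
    """Weighted least-squares fit of the second-order low-pass gain model.

    Parameters
    ----------
    freqs, gain_mag
        Frequency grid (Hz) and measured gain magnitude.
    coherence_weights
        Per-frequency weights in [0, 1]; squared residuals are multiplied by
        them (uniform if omitted).
    freq_range
        Only bins within ``[lo, hi]`` Hz enter the fit; the DC bin is always
        excluded.
    exclude_band
        Optional band (Hz) removed from the fit — by default the
        150 Hz mains-artefact band.
    n_restarts
        Jittered restarts around the data-driven initial guess; the seed
        makes them reproducible.
    log_magnitude
        Fit residuals of log gain instead of gain.
    """
    freqs = np.asarray(freqs, dtype=float)
    gain = np.asarray(gain_mag, dtype=float)
    if coherence_weights is None:
        w = np.ones_like(freqs)
    else:
        w = np.asarray(coherence_weights, dtype=float)
        require(np.all((w >= 0) & (w <= 1.000001)), "weights must lie in [0, 1]")
    mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1]) & (freqs > 0)
    if exclude_band is not None:
        mask &= ~((freqs >= exclude_band[0]) & (freqs <= exclude_band[1]))
    mask &= np.isfinite(gain) & (gain > 0)
    if mask.sum() < 10:
        raise InvalidArgumentError(
            f"need >= 10 usable frequency bins in range, have {int(mask.sum())}"
        )
    fm, gm, wm = freqs[mask], gain[mask], np.clip(w[mask], 0.0, 1.0)
    sw = np.sqrt(wm)

    def residuals(logp: np.ndarray) -> np.ndarray:
        beta, tau, zeta = np.exp(logp)
        pred = model_gain(fm, beta, tau, zeta)
        if log_magnitude:
            return sw * (np.log(pred) - np.log(gm))
        return sw * (pred - gm)

    beta0, tau0, zeta0 = _initial_guess(fm, gm)
    rng = np.random.default_rng(seed)
    starts = [np.log([beta0, tau0, zeta0])]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, [0.3, 0.4, 0.5])
        starts.append(np.log([beta0, tau0, zeta0]) + jitter)

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise EstimationError("gain fit failed to converge from every start")
    beta, tau, zeta = np.exp(best.x)
    return FilterFitResult(
        beta=float(beta), tau=float(tau), zeta=float(zeta),
        weighted_rss=float(2.0 * best.cost), n_freqs=int(mask.sum()),
        converged=bool(best.success), freq_range=tuple(freq_range),
        n_starts=len(starts),
    )


def normalize_beta(betas_by_condition: dict[str, float]) -> dict[str, float]:
    """Normalise one animal's fitted amplitudes by their across-condition
    maximum, so the largest condition maps to 1.0."""
    require(len(betas_by_condition) >= 2, "need >= 2 conditions per animal")
    peak = max(betas_by_condition.values())
    if not peak > 0:
        raise InvalidArgumentError("maximum beta must be positive")
    return {k: v / peak for k, v in betas_by_condition.items()}
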