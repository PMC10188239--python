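import numpy as np
import pytest

from ergpipe.core import TimeSeries
from ergpipe.stimulus import butterworth_lowpass, generate_white_noise
from ergpipe.synthetic import (CohortSpec, WALKING_EPOCH_PARAMS,
                               WALKING_LATENCY_MS, simulate_cohort,
                               walking_protocol)


@pytest.fixture(scope="session")
def bandlimited_noise() -> TimeSeries:
    """10 s of 250 Hz band-limited Gaussian noise at 3 kHz."""
    return butterworth_lowpass(generate_white_noise(10.0, 3000.0, seed=11))


@pytest.fixture(scope="session")
def small_walking_cohort():
    """Three short walking sessions generated with the condition-median
    filter parameters (shared across tests; treat as read-only)."""
    proto = walking_protocol(before_s=20.0, active_s=20.0, after_s=20.0)
    spec = CohortSpec(n_animals=3, protocol=proto, seed=5,
                      epoch_params=WALKING_EPOCH_PARAMS,
                      latency_medians=WALKING_LATENCY_MS,
                      snr=2.0, artefact_rel_amp=0.05)
    return simulate_cohort(spec)


def delayed_inverted_copy(ts: TimeSeries, delay_ms: float, snr: float = np.inf,
                          seed: int = 0) -> TimeSeries:
    """Sign-inverted copy of ``ts`` delayed by a (fractional-sample) lag."""
    t = ts.times
    y = -np.interp(t - delay_ms / 1000.0, t, ts.samples)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, float(np.std(ts.samples)) / snr, y.size)
    return TimeSeries(y, ts.rate, ts.t0)
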