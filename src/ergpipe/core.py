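"""Core containers for the analysis: uniformly sampled channels, recording
sessions with condition epochs, and the exception hierarchy shared by all
stages.

Every signal in the pipeline — photodiode-measured light stimulus, ERG
voltage, eye temperature, forward locomotion — travels as a
:class:`TimeSeries`.  A :class:`Session` bundles the four channels recorded
from one animal together with the condition epochs (sitting before, active
walking/heating, sitting after) and protocol metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "Epoch",
    "Session",
    "InvalidArgumentError",
    "EstimationError",
    "SchemaError",
    "BoundaryWarning",
    "RangeWarning",
]


class InvalidArgumentError(ValueError):
    """An argument violates a precondition (non-positive rate, corner above
    Nyquist, overlapping pulses, ...)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a value (zero-variance segment, all
    pulses missing, fewer than two spectral segments, non-convergence)."""


class SchemaError(KeyError):
    """A session container is missing required channels or metadata."""


class BoundaryWarning(UserWarning):
    """A latency minimum fell on the edge of the searched lag range."""


class RangeWarning(UserWarning):
    """A model was evaluated outside its supported input range."""


@dataclass
class TimeSeries:
    """A uniformly sampled, finite-valued channel.

    Parameters
    ----------
    samples
        Channel values; converted to a float64 array.
    rate
        Sampling rate in samples per second; must be positive.
    t0
        Time of the first sample in seconds.
    units
        Free-text unit label (e.g. ``"mV"``, ``"photons/cm2/s"``).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")
        if not (self.rate > 0):
            raise InvalidArgumentError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n samples / rate)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray, **changes) -> "TimeSeries":
        """Copy of this series with new samples (and optional field changes)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64), **changes)

    def crop(self, start: float, stop: float) -> "TimeSeries":
        """Sub-series covering absolute times ``[start, stop)`` seconds."""
        if stop <= start:
            raise InvalidArgumentError("crop requires stop > start")
        i0 = int(np.ceil(round((start - self.t0) * self.rate, 9)))
        i1 = int(np.ceil(round((stop - self.t0) * self.rate, 9)))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        if i1 <= i0:
            raise InvalidArgumentError(
                f"crop window [{start}, {stop}) s lies outside the series"
            )
        return TimeSeries(self.samples[i0:i1], self.rate, self.t0 + i0 / self.rate, self.units)


@dataclass(frozen=True)
class Epoch:
    """A labelled condition interval ``[start, end)`` in session time."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise InvalidArgumentError("epoch end must exceed start")


#: Canonical epoch labels in presentation order.
EPOCH_LABELS = ("before", "active", "after")


@dataclass
class Session:
    """Per-animal recording bundle.

    ``channels`` must contain the four named channels ``stimulus`` (photodiode
    trace), ``erg``, ``temperature`` and ``motion``; rates may differ between
    channels but all share ``t0`` and jointly cover every epoch.
    """

    animal_id: str
    channels: dict[str, TimeSeries]
    epochs: list[Epoch]
    protocol: str = "walking"
    intensity: float = float("nan")
    meta: dict = field(default_factory=dict)

    REQUIRED_CHANNELS = ("stimulus", "erg", "temperature", "motion")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise SchemaError(f"session missing channels: {missing}")
        epochs = sorted(self.epochs, key=lambda e: e.start)
        for a, b in zip(epochs, epochs[1:]):
            if b.start < a.end - 1e-9:
                raise InvalidArgumentError(
                    f"epochs overlap: {a.label}[{a.start},{a.end}) and "
                    f"{b.label}[{b.start},{b.end})"
                )
        self.epochs = epochs
        t0s = {round(ts.t0, 9) for ts in self.channels.values()}
        if len(t0s) > 1:
            raise InvalidArgumentError("all channels must share t0")

    def epoch(self, label: str) -> Epoch:
        """First epoch with the given label."""
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labelled {label!r}")

    @property
    def duration(self) -> float:
        return max(ts.t0 + ts.duration for ts in self.channels.values())


def require(condition: bool, message: str) -> None:
    """Raise :class:`InvalidArgumentError` unless ``condition`` holds."""
    if not condition:
        raise InvalidArgumentError(message)
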