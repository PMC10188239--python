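"""Session container I/O and condition segmentation.

Sessions are stored in an HDF5 container with one group per channel
(``samples`` float64 dataset; ``rate``, ``t0``, ``units`` attributes), an
``epochs`` table and protocol attributes.  Channels can also be exported
to / imported from two-column delimited text (time_s, value) for
interoperability with lab software exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .core import Epoch, InvalidArgumentError, SchemaError, Session, TimeSeries, require

__all__ = [
    "write_session",
    "read_session",
    "write_channel_text",
    "read_channel_text",
    "SegmentPolicy",
    "segment_conditions",
    "derive_epochs_from_motion",
]


def write_session(session: Session, path) -> None:
    """Write a session to an HDF5 container (lossless, float64)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["animal_id"] = session.animal_id
        f.attrs["protocol"] = session.protocol
        f.attrs["intensity"] = session.intensity
        f.attrs["meta"] = json.dumps(session.meta, default=lambda o: list(o))
        for name, ts in session.channels.items():
            g = f.create_group(f"channels/{name}")
            g.create_dataset("samples", data=ts.samples, dtype="float64")
            g.attrs["rate"] = ts.rate
            g.attrs["t0"] = ts.t0
            g.attrs["units"] = ts.units
        ep = np.array([(e.label.encode(), e.start, e.end) for e in session.epochs],
                      dtype=[("label", "S16"), ("start", "f8"), ("end", "f8")])
        f.create_dataset("epochs", data=ep)


def read_session(path) -> Session:
    """Read a session container; raises :class:`SchemaError` naming any
    missing required channel."""
    with h5py.File(path, "r") as f:
        if "channels" not in f:
            raise SchemaError("container has no 'channels' group")
        channels = {}
        for name in f["channels"]:
            g = f[f"channels/{name}"]
            channels[name] = TimeSeries(
                g["samples"][()], float(g.attrs["rate"]),
                float(g.attrs["t0"]), str(g.attrs["units"]),
            )
        missing = [c for c in Session.REQUIRED_CHANNELS if c not in channels]
        if missing:
            raise SchemaError(f"session container missing channels: {missing}")
        epochs = [Epoch(r["label"].decode(), float(r["start"]), float(r["end"]))
                  for r in f["epochs"][()]] if "epochs" in f else []
        meta = json.loads(f.attrs.get("meta", "{}"))
        return Session(
            animal_id=str(f.attrs.get("animal_id", "")), channels=channels,
            epochs=epochs, protocol=str(f.attrs.get("protocol", "")),
            intensity=float(f.attrs.get("intensity", np.nan)), meta=meta,
        )


def write_channel_text(ts: TimeSeries, path, fmt: str = "%.9g") -> None:
    """Two-column delimited text export: time_s <TAB> value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.column_stack([ts.times, ts.samples]), fmt=fmt,
               delimiter="\t", header="time_s\tvalue", comments="# ")


def read_channel_text(path, units: str = "") -> TimeSeries:
    """Read a two-column (time_s, value) text export back into a series.

    The rate is inferred from the median time step; times must be uniform
    to within 1e-6 of a step.
    """
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise SchemaError("expected two columns (time_s, value) with >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    # span-based step estimate is robust to per-value text rounding
    dt = float(t[-1] - t[0]) / (len(t) - 1)
    require(dt > 0, "time column must be increasing")
    if np.max(np.abs(np.diff(t) - dt)) > 1e-3 * dt:  # text precision slack
        raise SchemaError("time column is not uniformly sampled")
    return TimeSeries(v, 1.0 / dt, float(t[0]), units)


@dataclass(frozen=True)
class SegmentPolicy:
    """How the three evaluation segments are placed.

    ``window_s`` is the segment length; the *before* segment ends at the
    active-epoch onset, the *post-active* segment depends on
    ``active_mode`` — ``"post"`` takes the window immediately after the
    active epoch (the choice for real recordings, where walking artefacts
    contaminate the ERG), ``"in"`` takes the tail of the active epoch
    itself (appropriate for artefact-free synthetic data) — and the
    *recovery* segment starts ``recovery_min_s`` after the active epoch
    ends.
    """

    window_s: float = 5.0
    recovery_min_s: float = 300.0
    active_mode: str = "post"   # "post" | "in"

    def __post_init__(self) -> None:
        require(self.window_s >= 1.0, "window must be >= 1 s")
        require(self.active_mode in ("post", "in"), "active_mode must be 'post' or 'in'")


def segment_conditions(session: Session, policy: SegmentPolicy = SegmentPolicy()
                       ) -> dict[str, tuple[float, float] | None]:
    """Evaluation segments for the three conditions.

    Returns ``{"before": (t0, t1), "active": (t0, t1), "after": (t0, t1) or
    None}``; the recovery segment is ``None`` (flagged unavailable) when the
    recording is too short to place it ``recovery_min_s`` after activity.
    """
    before = session.epoch("before")
    active = session.epoch("active")
    after = session.epoch("after")
    w = policy.window_s
    seg_before = (max(before.start, active.start - w), active.start)
    if policy.active_mode == "in":
        seg_active = (max(active.start, active.end - w), active.end)
    else:
        seg_active = (active.end, min(active.end + w, after.end))
    rec_start = active.end + policy.recovery_min_s
    seg_after = (rec_start, rec_start + w) if rec_start + w <= after.end + 1e-9 else None
    return {"before": seg_before, "active": seg_active, "after": seg_after}


def derive_epochs_from_motion(session: Session, threshold: float = 0.25,
                              min_duration_s: float = 2.0) -> list[Epoch]:
    """Derive before/active/after epochs from the locomotion channel:
    walking is forward speed above ``threshold`` sustained for at least
    ``min_duration_s``."""
    motion = session.channels["motion"]
    above = motion.samples > threshold
    rate = motion.rate
    min_n = int(round(min_duration_s * rate))
    # longest run of sustained activity
    best = None
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_n and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    total = motion.t0 + motion.duration
    if best is None:
        return [Epoch("before", motion.t0, total)]
    t_on, t_off = motion.t0 + best[0] / rate, motion.t0 + best[1] / rate
    eps = []
    if t_on > motion.t0:
        eps.append(Epoch("before", motion.t0, t_on))
    eps.append(Epoch("active", t_on, t_off))
    if t_off < total:
        eps.append(Epoch("after", t_off, total))
    return eps
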