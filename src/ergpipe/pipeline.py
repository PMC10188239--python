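"""Analysis orchestration: chain segmentation, latency estimation, spectral
estimation and filter fitting over whole cohorts, then run the condition
statistics, and write tidy tables, figures and a markdown report.

Everything here is deterministic given the configuration seed; every row of
every output table carries the session id and evaluation segment it came
from, and a structured JSON-lines log records each decision (segments
chosen, fit restarts, failures).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .core import BoundaryWarning, EstimationError, InvalidArgumentError, Session
from .filter_fit import ARTEFACT_BAND, DEFAULT_FIT_RANGE, fit_gain, normalize_beta
from .latency import cross_correlate, pulse_latency_half_max, xcorr_latency
from .session_io import SegmentPolicy, read_session, segment_conditions
from .spectral import (DEFAULT_RESAMPLE_MS, DEFAULT_SEGMENT_LEN, estimate_spectra,
                       gain_magnitude, resample_uniform)
from .stats import paired_wilcoxon_bonferroni

__all__ = ["AnalysisConfig", "analyze_segment", "analyze_session",
           "analyze_cohort", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Full configuration of one analysis run (YAML-serialisable)."""

    segment_window_s: float = 5.0
    recovery_min_s: float = 300.0
    active_mode: str = "post"
    resample_interval_ms: float = DEFAULT_RESAMPLE_MS
    spectral_segment_len: int = DEFAULT_SEGMENT_LEN
    spectral_window: str = "hann"
    spectral_overlap: float = 0.5
    fit_freq_range: tuple[float, float] = DEFAULT_FIT_RANGE
    artefact_band: Optional[tuple[float, float]] = ARTEFACT_BAND
    fit_restarts: int = 5
    max_lag_ms: float = 30.0
    latency_search_ms: tuple[float, float] = (0.0, 30.0)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"

    @property
    def segment_policy(self) -> SegmentPolicy:
        return SegmentPolicy(self.segment_window_s, self.recovery_min_s,
                             self.active_mode)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("fit_freq_range", "artefact_band", "latency_search_ms"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg


def analyze_segment(session: Session, segment: tuple[float, float],
                    condition: str, config: AnalysisConfig) -> dict:
    """Latency + spectral fit for one evaluation segment of one session."""
    stim = session.channels["stimulus"].crop(*segment)
    erg = session.channels["erg"].crop(*segment)
    try:
        temp = float(np.mean(session.channels["temperature"].crop(*segment).samples))
    except InvalidArgumentError:
        temp = float("nan")
    row: dict = {
        "animal": session.animal_id, "condition": condition,
        "segment_start": segment[0], "segment_end": segment[1],
        "temperature_C": temp, "intensity": session.intensity,
        "treatment": session.meta.get("treatment", ""),
    }
    onsets = [t for t in session.meta.get("pulse_onsets", [])
              if segment[0] <= t < segment[1] - 0.05]
    if onsets:
        row["method"] = "pulse_halfmax"
        try:
            row["latency_ms"] = pulse_latency_half_max(erg, onsets)
        except EstimationError:
            row["latency_ms"] = float("nan")
        return row
    row["method"] = "xcorr"
    try:
        c = cross_correlate(stim, erg, config.max_lag_ms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BoundaryWarning)
            row["latency_ms"] = xcorr_latency(c, config.latency_search_ms)
    except (EstimationError, InvalidArgumentError):
        row["latency_ms"] = float("nan")
    try:
        xr = resample_uniform(stim, config.resample_interval_ms)
        yr = resample_uniform(erg, config.resample_interval_ms)
        est = estimate_spectra(xr, yr, config.spectral_segment_len,
                               config.spectral_window, config.spectral_overlap)
        freqs, gmag = gain_magnitude(est)
        fit = fit_gain(freqs, gmag, est.coherence[1:], config.fit_freq_range,
                       config.artefact_band, config.fit_restarts, config.seed)
        row.update(beta=fit.beta, tau_ms=fit.tau, zeta=fit.zeta,
                   weighted_rss=fit.weighted_rss, n_freqs=fit.n_freqs,
                   converged=fit.converged, n_spec_segments=est.n_segments)
    except (EstimationError, InvalidArgumentError):
        row.update(beta=np.nan, tau_ms=np.nan, zeta=np.nan,
                   weighted_rss=np.nan, n_freqs=0, converged=False)
    return row


def analyze_session(session: Session, config: AnalysisConfig,
                    log: list | None = None) -> list[dict]:
    """All three condition segments of one session."""
    segments = segment_conditions(session, config.segment_policy)
    rows = []
    for condition, seg in segments.items():
        if seg is None:
            if log is not None:
                log.append({"event": "segment_unavailable",
                            "animal": session.animal_id, "condition": condition})
            continue
        if log is not None:
            log.append({"event": "segment", "animal": session.animal_id,
                        "condition": condition, "start": seg[0], "end": seg[1]})
        rows.append(analyze_segment(session, seg, condition, config))
    return rows


def analyze_cohort(sessions: Iterable[Session], config: AnalysisConfig,
                   log: list | None = None) -> pd.DataFrame:
    """Per-animal, per-condition result table for a cohort.

    Failures in one session are logged and the analysis continues with the
    remaining animals.  Adds the per-animal amplitude normalisation
    (beta / max beta across that animal's conditions).
    """
    rows = []
    for session in sessions:
        try:
            rows.extend(analyze_session(session, config, log))
        except Exception as exc:  # keep going for the remaining animals
            if log is not None:
                log.append({"event": "session_failed",
                            "animal": getattr(session, "animal_id", "?"),
                            "error": repr(exc)})
    df = pd.DataFrame(rows)
    if not df.empty and "beta" in df:
        norms = []
        for animal, grp in df.groupby("animal"):
            betas = {r.condition: r.beta for r in grp.itertuples()
                     if np.isfinite(getattr(r, "beta", np.nan))}
            if len(betas) >= 2:
                bn = normalize_beta(betas)
            else:
                bn = {}
            for r in grp.itertuples():
                norms.append((r.Index, bn.get(r.condition, np.nan)))
        df["beta_norm"] = pd.Series(dict(norms))
    return df


def _condition_stats(df: pd.DataFrame, value: str, alpha: float) -> pd.DataFrame:
    wide = df.pivot_table(index="animal", columns="condition", values=value)
    wide = wide.dropna()
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return pd.DataFrame()
    contrasts = [(a, b) for a, b in (("before", "active"), ("after", "active"),
                                     ("before", "after"))
                 if a in wide.columns and b in wide.columns]
    comps = paired_wilcoxon_bonferroni(wide, contrasts, alpha)
    return pd.DataFrame([{**vars(c), "value": value} for c in comps])


def run_pipeline(config: AnalysisConfig, sessions: Iterable[Session] | None = None,
                 session_paths: Iterable = (), make_figures: bool = True) -> dict:
    """Full run: per-animal tables, condition statistics, figures, report.

    Sessions may be passed in memory or as HDF5 paths.  Outputs are written
    under ``config.out_dir``; the returned dict carries the tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def iter_sessions():
        if sessions is not None:
            yield from sessions
        for p in session_paths:
            yield read_session(p)

    table = analyze_cohort(iter_sessions(), config, log)
    if table.empty:
        raise EstimationError("no session produced any analysable segment")
    table = table.sort_values(["animal", "condition"]).reset_index(drop=True)
    table.to_csv(out / "per_animal.csv", index=False, float_format="%.6g")

    stats_frames = []
    for value in ("latency_ms", "tau_ms", "zeta", "beta_norm"):
        if value in table:
            s = _condition_stats(table.dropna(subset=[value]), value, config.alpha)
            if not s.empty:
                stats_frames.append(s)
    stats_table = (pd.concat(stats_frames, ignore_index=True)
                   if stats_frames else pd.DataFrame())
    stats_table.to_csv(out / "condition_stats.csv", index=False, float_format="%.6g")

    medians = table.groupby("condition")[
        [c for c in ("latency_ms", "tau_ms", "zeta", "beta_norm", "temperature_C")
         if c in table]].median()
    medians.to_csv(out / "condition_medians.csv", float_format="%.6g")

    with open(out / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    config.to_yaml(out / "config.yaml")

    if make_figures:
        _write_figures(table, out)

    report = _render_report(table, medians, stats_table)
    (out / "report.md").write_text(report)
    return {"per_animal": table, "condition_stats": stats_table,
            "condition_medians": medians, "log": log, "out_dir": str(out)}


def _write_figures(table: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [c for c in ("before", "active", "after") if c in set(table["condition"])]
    for value, label in (("latency_ms", "latency (ms)"), ("tau_ms", "tau (ms)"),
                         ("zeta", "damping"),):
        if value not in table or table[value].dropna().empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        data = [table.loc[table["condition"] == c, value].dropna() for c in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(out / f"box_{value}.png", dpi=120)
        plt.close(fig)


def _render_report(table: pd.DataFrame, medians: pd.DataFrame,
                   stats_table: pd.DataFrame) -> str:
    lines = ["# ERG analysis run", "",
             f"Animals: {table['animal'].nunique()}; rows: {len(table)}", "",
             "## Condition medians", "", medians.to_markdown(), ""]
    if not stats_table.empty:
        lines += ["## Paired Wilcoxon (Bonferroni-corrected)", "",
                  stats_table.to_markdown(index=False), ""]
    return "\n".join(lines)
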