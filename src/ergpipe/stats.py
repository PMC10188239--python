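"""Condition comparisons and the latency–temperature mixed model.

Three analyses:

* Paired Wilcoxon signed-rank tests across the three condition epochs with
  Bonferroni correction (three contrasts, so alpha 0.05 -> 0.0167).
* A linear mixed-effects model of latency on eye temperature with a
  treatment (walking vs heated) fixed effect and per-animal random
  intercepts and temperature slopes; candidate models are compared by
  likelihood-ratio test and AIC, and confidence intervals for the selected
  model's coefficients come from a cluster (by-animal) bootstrap.
* The intensity–latency summary: per-intensity medians, the
  highest-vs-lowest latency difference, and the walking-vs-sitting latency
  effect for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import EstimationError, InvalidArgumentError, require

__all__ = [
    "PairedComparison",
    "RegressionResult",
    "paired_wilcoxon_bonferroni",
    "fit_latency_temperature_model",
    "intensity_latency_summary",
    "DEFAULT_CONTRASTS",
]

#: The three condition contrasts tested by default.
DEFAULT_CONTRASTS = (("before", "active"), ("after", "active"), ("before", "after"))


@dataclass
class PairedComparison:
    """One paired signed-rank contrast."""

    contrast: str
    n_pairs: int
    statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool


@dataclass
class RegressionResult:
    """Selected latency–temperature mixed model and its competitors."""

    intercept: float                      # ms
    slope: float                          # ms per degC
    treatment_offset: float               # ms (heated relative to walking)
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    treatment_se: float
    model_name: str
    aic_table: dict[str, float]
    lrt_table: list[dict]
    random_effects_sd: dict[str, float]
    n_animals: int
    n_obs: int
    converged: bool
    notes: list[str] = field(default_factory=list)


def paired_wilcoxon_bonferroni(values: pd.DataFrame, contrasts=DEFAULT_CONTRASTS,
                               alpha: float = 0.05) -> list[PairedComparison]:
    """Paired Wilcoxon signed-rank tests with Bonferroni correction.

    ``values`` is a wide table: one row per animal, one column per
    condition.  p-values are exact for n <= 25 (when the differences are
    tie-free), normal-approximated otherwise; the corrected threshold is
    ``alpha`` divided by the number of contrasts.
    """
    m = len(contrasts)
    require(m >= 1, "need at least one contrast")
    alpha_corr = alpha / m
    out = []
    for a, b in contrasts:
        if a not in values.columns or b not in values.columns:
            raise InvalidArgumentError(f"missing condition column for contrast {a}-{b}")
        da = values[a].to_numpy(dtype=float)
        db = values[b].to_numpy(dtype=float)
        if np.any(np.isnan(da)) or np.any(np.isnan(db)):
            raise InvalidArgumentError("unpaired/missing animals in contrast table")
        diff = da - db
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            n_eff = np.count_nonzero(diff)
            method = "exact" if n_eff <= 25 else "approx"
            try:
                res = sps.wilcoxon(da, db, zero_method="wilcox", method=method)
            except ValueError:
                res = sps.wilcoxon(da, db, zero_method="wilcox", method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        out.append(PairedComparison(
            contrast=f"{a}-{b}", n_pairs=len(da), statistic=stat, p_value=p,
            alpha_corrected=alpha_corr, significant=bool(p < alpha_corr),
        ))
    return out


_CANDIDATES = {
    "null": "latency ~ 1",
    "temperature": "latency ~ temperature",
    "temperature+treatment": "latency ~ temperature + C(treatment, Treatment('walking'))",
    "temperature*treatment": "latency ~ temperature * C(treatment, Treatment('walking'))",
}


def _fit_mixed(df: pd.DataFrame, formula: str, reml: bool,
               re_formula: str = "~temperature"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, df, groups=df["animal"], re_formula=re_formula)
        return model.fit(reml=reml, method=["lbfgs", "powell"])


def fit_latency_temperature_model(measurements: pd.DataFrame,
                                  n_boot: int = 200, seed: int = 0,
                                  alpha: float = 0.05) -> RegressionResult:
    """Fit and select the latency–temperature mixed-effects model.

    ``measurements`` needs columns ``animal``, ``treatment``,
    ``temperature`` (degC) and ``latency`` (ms), with at least two animals
    and at least two temperatures per animal.  Random structure:
    per-animal intercept and temperature slope (falling back to a random
    intercept only if the full structure is singular).  Candidates — null,
    +temperature, +treatment, +interaction — are compared with ML
    likelihood-ratio tests and AIC; the selected model is refit by REML and
    its fixed effects get percentile CIs from ``n_boot`` by-animal
    bootstrap resamples.
    """
    df = measurements.copy()
    for col in ("animal", "treatment", "temperature", "latency"):
        require(col in df.columns, f"measurements missing column {col!r}")
    require(df["animal"].nunique() >= 2, "need >= 2 animals")
    require((df.groupby("animal")["temperature"].nunique() >= 2).all(),
            "need >= 2 temperatures per animal")
    notes: list[str] = []
    re_formula = "~temperature"

    candidates = dict(_CANDIDATES)
    two_groups = df["treatment"].nunique() >= 2 and "walking" in set(df["treatment"])
    if not two_groups:
        candidates = {k: v for k, v in candidates.items() if "treatment" not in k}
        notes.append("single treatment group: treatment terms not considered")

    fits_ml = {}
    for name, formula in candidates.items():
        try:
            fits_ml[name] = _fit_mixed(df, formula, reml=False, re_formula=re_formula)
        except Exception:
            if re_formula != "~1":
                notes.append("random-slope fit singular; fell back to random intercept only")
                re_formula = "~1"
                fits_ml[name] = _fit_mixed(df, formula, reml=False, re_formula=re_formula)
            else:
                raise EstimationError(f"mixed model {name!r} failed to fit")

    def aic(fit) -> float:
        k = fit.df_modelwc
        return float(2 * k - 2 * fit.llf)

    aic_table = {name: aic(fit) for name, fit in fits_ml.items()}
    order = [n for n in ("null", "temperature", "temperature+treatment",
                         "temperature*treatment") if n in fits_ml]
    lrt_table = []
    for simpler, fuller in zip(order, order[1:]):
        f0, f1 = fits_ml[simpler], fits_ml[fuller]
        dd = float(2 * (f1.llf - f0.llf))
        dof = int(f1.df_modelwc - f0.df_modelwc)
        p = float(sps.chi2.sf(max(dd, 0.0), max(dof, 1)))
        lrt_table.append({"comparison": f"{simpler} vs {fuller}",
                          "delta_deviance": dd, "df": dof, "p_value": p})
    selected = min(aic_table, key=aic_table.get)

    final = _fit_mixed(df, candidates[selected], reml=True, re_formula=re_formula)
    params = final.params
    intercept = float(params.get("Intercept", np.nan))
    slope = float(params.get("temperature", 0.0))
    # the treatment contrast is always reported from the +treatment model so a
    # small offset remains quantified even when AIC prefers the simpler model
    treatment_offset, treatment_se = 0.0, float("nan")
    if two_groups:
        treat_fit = (final if "treatment" in selected
                     else _fit_mixed(df, candidates["temperature+treatment"],
                                     reml=True, re_formula=re_formula))
        treat_name = next((k for k in treat_fit.params.index
                           if k.startswith("C(treatment")), None)
        if treat_name:
            # walking is the reference level, so this is heated minus walking
            treatment_offset = float(treat_fit.params[treat_name])
            treatment_se = float(treat_fit.bse[treat_name])

    rng = np.random.default_rng(seed)
    animals = df["animal"].unique()
    boot = {"Intercept": [], "temperature": []}
    for _ in range(n_boot):
        chosen = rng.choice(animals, size=animals.size, replace=True)
        parts = []
        for j, a in enumerate(chosen):
            part = df[df["animal"] == a].copy()
            part["animal"] = f"b{j:03d}"
            parts.append(part)
        bdf = pd.concat(parts, ignore_index=True)
        try:
            bf = _fit_mixed(bdf, candidates[selected], reml=True, re_formula=re_formula)
        except Exception:
            continue
        boot["Intercept"].append(float(bf.params.get("Intercept", np.nan)))
        boot["temperature"].append(float(bf.params.get("temperature", np.nan)))
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))

    def ci(key: str, point: float) -> tuple[float, float]:
        vals = np.asarray([v for v in boot[key] if np.isfinite(v)])
        if vals.size < 10:
            return (point, point)
        lo, hi = np.percentile(vals, qs)
        return (float(lo), float(hi))

    re_sd = {}
    try:
        cov_re = final.cov_re
        for nm in cov_re.index:
            re_sd[nm] = float(np.sqrt(cov_re.loc[nm, nm]))
    except Exception:
        pass

    return RegressionResult(
        intercept=intercept, slope=slope, treatment_offset=treatment_offset,
        intercept_ci=ci("Intercept", intercept), slope_ci=ci("temperature", slope),
        treatment_se=treatment_se, model_name=selected, aic_table=aic_table,
        lrt_table=lrt_table, random_effects_sd=re_sd,
        n_animals=int(df["animal"].nunique()), n_obs=len(df),
        converged=bool(final.converged), notes=notes,
    )


def intensity_latency_summary(measurements: pd.DataFrame,
                              walking_medians: tuple[float, float] = (9.0, 7.4)
                              ) -> dict:
    """Per-intensity median latencies and the intensity effect.

    ``measurements`` needs columns ``intensity`` and ``latency_ms``.
    Returns per-intensity medians (ascending intensity), a monotonicity
    flag, the highest-vs-lowest latency difference, and — for comparison —
    the walking effect computed from the supplied sitting/walking noise
    medians.
    """
    require("intensity" in measurements and "latency_ms" in measurements,
            "measurements need intensity and latency_ms columns")
    med = (measurements.groupby("intensity")["latency_ms"].median().sort_index())
    require(len(med) >= 1, "no intensities present")
    diffs = {}
    levels = list(med.index)
    for a, b in zip(levels, levels[1:]):
        diffs[f"{a:.3g}->{b:.3g}"] = float(med[a] - med[b])
    sitting, walking = walking_medians
    return {
        "medians_ms": {float(k): float(v) for k, v in med.items()},
        "monotone_decreasing": bool(np.all(np.diff(med.to_numpy()) <= 0)),
        "highest_vs_lowest_ms": float(med.iloc[0] - med.iloc[-1]),
        "pairwise_differences_ms": diffs,
        "walking_effect_ms": float(sitting - walking),
    }
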