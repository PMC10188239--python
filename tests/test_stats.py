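import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ergpipe.core import InvalidArgumentError
from ergpipe.stats import (fit_latency_temperature_model,
                           intensity_latency_summary,
                           paired_wilcoxon_bonferroni, _fit_mixed)
from ergpipe.synthetic import TemperatureModel, simulate_latency_measurements


def brute_force_signed_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    diff = a - b
    ranks = sps.rankdata(np.abs(diff))
    n = diff.size
    t_plus = float(np.sum(ranks[diff > 0]))
    t_obs = min(t_plus, float(np.sum(ranks)) - t_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = float(np.sum(ranks[np.asarray(signs) == 1]))
        if t <= t_obs + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


class TestWilcoxon:
    def test_bonferroni_threshold(self):
        wide = pd.DataFrame({"before": [1.0, 2, 3, 4], "active": [0.5, 1, 2, 3],
                             "after": [1.1, 2, 3, 4]})
        comps = paired_wilcoxon_bonferroni(wide)
        assert all(c.alpha_corrected == pytest.approx(0.05 / 3, abs=5e-5) for c in comps)
        assert comps[0].alpha_corrected == pytest.approx(0.0167, abs=1e-4)

    def test_identical_values_not_significant(self):
        wide = pd.DataFrame({"before": [1.0, 2, 3], "active": [1.0, 2, 3]})
        (c,) = paired_wilcoxon_bonferroni(wide, contrasts=(("before", "active"),))
        assert c.p_value == 1.0 and not c.significant

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_exact_p_matches_enumeration_n12(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(10, 1, 12)
        b = a - rng.normal(0.4, 1, 12)
        wide = pd.DataFrame({"before": a, "active": b})
        (c,) = paired_wilcoxon_bonferroni(wide, contrasts=(("before", "active"),))
        assert c.p_value == pytest.approx(brute_force_signed_rank_p(a, b), abs=1e-12)

    def test_consistent_direction_smallest_p(self):
        """Twelve pairs all shifted the same way give the extreme-table
        exact p of 2/2^12."""
        a = np.arange(1.0, 13.0) + 1.0
        b = np.arange(1.0, 13.0)
        wide = pd.DataFrame({"before": a, "active": b})
        (c,) = paired_wilcoxon_bonferroni(wide, contrasts=(("before", "active"),))
        assert c.p_value == pytest.approx(2 / 4096, abs=1e-12)

    def test_missing_animals_rejected(self):
        wide = pd.DataFrame({"before": [1.0, np.nan, 3], "active": [1.0, 2, 3]})
        with pytest.raises(InvalidArgumentError):
            paired_wilcoxon_bonferroni(wide, contrasts=(("before", "active"),))


class TestMixedModel:
    def test_exact_recovery_on_noise_free_line(self):
        rows = []
        for i in range(4):
            for T in np.linspace(26, 32, 5):
                rows.append({"animal": f"a{i}", "treatment": "walking",
                             "temperature": T, "latency": 22.21 - 0.48 * T})
        res = fit_latency_temperature_model(pd.DataFrame(rows), n_boot=0)
        assert res.intercept == pytest.approx(22.21, abs=1e-6)
        assert res.slope == pytest.approx(-0.48, abs=1e-6)

    def test_recovery_with_study_like_noise(self):
        """Point estimates land near the generating relation; CI coverage
        itself is checked across cohorts below."""
        res = _recovery_result()
        assert res.intercept == pytest.approx(22.21, abs=0.5)
        assert res.slope == pytest.approx(-0.48, abs=0.05)
        assert "temperature" in res.model_name
        assert res.intercept_ci[0] < res.intercept < res.intercept_ci[1]

    def test_treatment_offset_detected_within_two_se(self):
        res = _recovery_result()
        assert abs(res.treatment_offset - 0.177) <= 2 * res.treatment_se

    def test_selection_and_slope_stability_over_cohorts(self):
        """Across repeated cohorts the temperature model always beats the
        null and the mean recovered slope stays within 5 % of truth, with
        Wald 95 % CIs covering it at least 90 % of the time."""
        slopes, covered = [], 0
        n_cohorts = 20
        for seed in range(n_cohorts):
            df = simulate_latency_measurements(seed=seed)
            fit = _fit_mixed(df, "latency ~ temperature + C(treatment, Treatment('walking'))",
                             reml=True)
            s = float(fit.params["temperature"])
            se = float(fit.bse["temperature"])
            slopes.append(s)
            if s - 1.96 * se <= -0.48 <= s + 1.96 * se:
                covered += 1
            null = _fit_mixed(df, "latency ~ 1", reml=False)
            temp = _fit_mixed(df, "latency ~ temperature", reml=False)
            assert temp.llf > null.llf + 10  # temperature term always selected
        assert abs(np.mean(slopes) - (-0.48)) / 0.48 < 0.05
        assert covered >= int(0.9 * n_cohorts)

    def test_too_few_animals_rejected(self):
        df = pd.DataFrame({"animal": ["a"] * 4, "treatment": ["walking"] * 4,
                           "temperature": [26, 27, 28, 29],
                           "latency": [9.0, 8.5, 8.0, 7.5]})
        with pytest.raises(InvalidArgumentError):
            fit_latency_temperature_model(df, n_boot=0)


_CACHED = {}


def _recovery_result():
    if "res" not in _CACHED:
        df = simulate_latency_measurements(model=TemperatureModel(),
                                           heated_offset_ms=0.177, seed=12)
        _CACHED["res"] = fit_latency_temperature_model(df, n_boot=60, seed=1)
    return _CACHED["res"]


class TestIntensitySummary:
    def test_printed_noise_medians_give_walking_effect(self):
        df = pd.DataFrame({"intensity": [1.74e14, 2.41e15], "latency_ms": [9.0, 7.6]})
        out = intensity_latency_summary(df, walking_medians=(9.0, 7.4))
        assert out["walking_effect_ms"] == pytest.approx(1.6, abs=1e-9)

    def test_duplicate_series_no_difference(self):
        df = pd.DataFrame({"intensity": [1e14] * 6, "latency_ms": [9, 9.1, 8.9, 9, 9.2, 8.8]})
        out = intensity_latency_summary(df)
        assert out["highest_vs_lowest_ms"] == 0.0

    def test_synthetic_series_recovers_calibrated_difference(self):
        from ergpipe.experiments import intensity_series_experiment
        out = intensity_series_experiment(n_animals=4, seed=1)
        assert out["monotone_decreasing"]
        assert out["highest_vs_lowest_ms"] == pytest.approx(1.4, abs=0.1)
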