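"""Simulation study: generators, analytic truths, scenario metrics."""

import math

import numpy as np
import pytest
from scipy import stats

from distprop import SimulationScenario, run_scenario, true_values
from distprop.exceptions import DomainError
from distprop.simulation import (cutpoint_for, generate, scenario_grid,
                                 summarize_grid)


class TestGenerate:
    def test_lognormal_low_logsd_is_nearly_symmetric(self):
        x = generate("lognormal", {"log_mean": 0.0, "log_sd": 0.02}, 200_000,
                     seed=11)
        s = 0.02
        target = (math.exp(s**2) + 2) * math.sqrt(math.expm1(s**2))
        assert target == pytest.approx(0.06, abs=0.001)
        assert stats.skew(x) == pytest.approx(target, abs=0.02)

    def test_lognormal_mean_median_ratio(self):
        # skewness gauge: E[X]/median = exp(log_sd^2 / 2)
        x = generate("lognormal", {"log_mean": 0.0, "log_sd": 1.0}, 400_000,
                     seed=12)
        assert x.mean() / np.median(x) == pytest.approx(math.exp(0.5), rel=0.02)

    def test_skew_normal_alpha_zero_is_normal(self):
        x = generate("skew_normal", {"mean": 0.0, "sd": 1.0, "alpha": 0.0},
                     10_000, seed=13)
        _, pval = stats.kstest(x, "norm")
        assert pval > 0.01

    def test_skew_normal_moments_match_request(self):
        x = generate("skew_normal", {"mean": 2.0, "sd": 3.0, "alpha": -6.0},
                     400_000, seed=14)
        assert x.mean() == pytest.approx(2.0, abs=0.02)
        assert x.std(ddof=1) == pytest.approx(3.0, rel=0.01)
        assert stats.skew(x) < -0.5

    def test_deterministic_given_seed(self):
        a = generate("lognormal", {"log_mean": 0.0, "log_sd": 0.5}, 100, seed=5)
        b = generate("lognormal", {"log_mean": 0.0, "log_sd": 0.5}, 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_invalid_family(self):
        with pytest.raises(DomainError):
            generate("gamma", {}, 10, seed=0)


class TestTruths:
    def test_cutpoint_hits_reference_quantile(self):
        sc = SimulationScenario(family="lognormal", skewness=0.6,
                                n_per_group=100, cutpoint_quantile=0.2, seed=1)
        x0 = cutpoint_for(sc)
        assert stats.lognorm.cdf(x0, s=0.6) == pytest.approx(0.2, abs=1e-9)
        tv = true_values(sc)
        assert tv["p_reference"] == pytest.approx(0.2, abs=1e-9)

    def test_zero_effect_gives_null_truths(self):
        sc = SimulationScenario(family="skew_normal", skewness=5.0,
                                n_per_group=100, effect_size=0.01, seed=1,
                                allow_outside_design=True)
        sc0 = SimulationScenario(family="skew_normal", skewness=5.0,
                                 n_per_group=100, effect_size=1e-12, seed=1,
                                 allow_outside_design=True)
        tv = true_values(sc0)
        assert tv["d"] == pytest.approx(0.0, abs=1e-10)
        assert tv["rr"] == pytest.approx(1.0, abs=1e-9)
        assert tv["or"] == pytest.approx(1.0, abs=1e-9)
        assert abs(true_values(sc)["d"]) > abs(tv["d"])

    def test_lognormal_truths_match_quadrature(self):
        from scipy import integrate
        sc = SimulationScenario(family="lognormal", skewness=0.8,
                                n_per_group=100, effect_size=0.3, seed=1)
        tv = true_values(sc)
        s = 0.8
        mean_ref = math.exp(s**2 / 2)
        sd_ref = mean_ref * math.sqrt(math.expm1(s**2))
        m_exp = math.log(mean_ref + 0.3 * sd_ref) - s**2 / 2
        val, _ = integrate.quad(
            lambda t: stats.lognorm.pdf(t, s=s, scale=math.exp(m_exp)),
            0, tv["cutpoint"])
        assert tv["p_exposed"] == pytest.approx(val, abs=1e-8)

    def test_skew_normal_truth_at_alpha_zero_equals_normal(self):
        sc = SimulationScenario(family="skew_normal", skewness=0.0,
                                n_per_group=100, effect_size=0.2,
                                cutpoint_quantile=0.1, seed=1)
        tv = true_values(sc)
        x0 = tv["cutpoint"]
        assert x0 == pytest.approx(stats.norm.ppf(0.1), abs=1e-9)
        assert tv["p_exposed"] == pytest.approx(stats.norm.cdf(x0 - 0.2), abs=1e-9)


class TestRunScenario:
    def test_normal_data_normal_method_calibrated(self):
        sc = SimulationScenario(family="skew_normal", skewness=0.0,
                                n_per_group=100, effect_size=0.2,
                                replicates=2000, seed=42, method="normal")
        m = run_scenario(sc)
        assert 0.93 <= m.d.coverage <= 0.96
        assert abs(m.d.rel_se_bias) < 0.1
        assert m.d.mean_estimate == pytest.approx(m.truths["d"], abs=0.01)
        assert m.n_failed == 0

    def test_zero_effect_mean_d_near_zero(self):
        sc = SimulationScenario(family="skew_normal", skewness=0.0,
                                n_per_group=100, effect_size=1e-9,
                                replicates=2000, seed=7, method="normal",
                                allow_outside_design=True)
        m = run_scenario(sc)
        mc_se = m.d.sd_estimate / math.sqrt(m.n_valid)
        assert abs(m.d.mean_estimate) < 4 * mc_se

    def test_seeded_determinism(self):
        sc = SimulationScenario(family="lognormal", skewness=0.4,
                                n_per_group=50, replicates=300, seed=99)
        assert run_scenario(sc) == run_scenario(sc)

    def test_skew_method_moments_runs(self):
        sc = SimulationScenario(family="skew_normal", skewness=5.0,
                                n_per_group=100, replicates=500, seed=3,
                                method="skew_normal",
                                shape_estimation="moments")
        m = run_scenario(sc)
        assert 0.8 <= m.d.coverage <= 1.0

    def test_design_range_enforced(self):
        with pytest.raises(DomainError):
            SimulationScenario(family="lognormal", skewness=3.0,
                               n_per_group=100, seed=1)
        with pytest.raises(DomainError):
            SimulationScenario(family="lognormal", skewness=0.5,
                               n_per_group=5000, seed=1)


class TestSummaries:
    def _metrics(self, n_scen=4):
        scs = scenario_grid("skew_normal", [0.0], [50],
                            effect_sizes=(0.1, 0.3), cutpoint_quantiles=(0.1, 0.2),
                            replicates=200, seed=5)
        assert len(scs) == n_scen
        return [run_scenario(sc) for sc in scs]

    def test_single_scenario_cell_degenerate(self):
        sc = SimulationScenario(family="lognormal", skewness=0.2,
                                n_per_group=50, replicates=200, seed=8)
        df = summarize_grid([run_scenario(sc)])
        row = df[df.estimand == "d"].iloc[0]
        assert row["coverage_iqr"] == 0.0
        assert row["n_scenarios"] == 1

    def test_quantile_rules_brute_force(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        # linear (type-7): position 2.25 -> 0.3 + 0.25*0.1
        assert np.quantile(vals, 0.75) == pytest.approx(0.325)
        from distprop.simulation import _quantile
        assert _quantile(vals, 0.75, "linear") == pytest.approx(0.325)
        assert _quantile(vals, 0.75, "nearest") == pytest.approx(0.3)
        with pytest.raises(DomainError):
            _quantile(vals, 0.75, "midpoint")

    def test_grid_summary_shape_and_columns(self):
        df = summarize_grid(self._metrics())
        assert set(df.estimand) == {"d", "rr", "or"}
        assert (df.n_scenarios == 4).all()
        assert (df.coverage_q3 >= df.coverage_q1).all()
        assert (df.q3_abs_bias >= 0).all()
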