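"""Distributional proportion/comparison estimates and their SEs."""

import math

import numpy as np
import pytest
from scipy import stats

from distprop import (DegenerateTailError, GroupSummary, PooledModel,
                      Threshold, compare_groups, dci,
                      distributional_proportion, pooled_sd)
from distprop.exceptions import ConfigError, DomainError


def _model(g1, g2, alpha=0.0):
    method = "normal" if alpha == 0.0 else "skew_normal"
    return PooledModel(groups=(g1, g2), sd_pooled=pooled_sd(g1, g2),
                       alpha=alpha, method=method)


class TestPooledSd:
    def test_equal_sds_pass_through(self):
        g1 = GroupSummary("a", 10, 0.0, 2.5)
        g2 = GroupSummary("b", 400, 1.0, 2.5)
        assert pooled_sd(g1, g2) == pytest.approx(2.5, rel=1e-14)

    def test_birthweight_pooling(self, birthweight_summaries):
        sp = pooled_sd(birthweight_summaries["reference"],
                       birthweight_summaries["exposed"])
        assert sp == pytest.approx(437.0146, abs=5e-4)

    def test_equal_weights_small_n(self):
        g1 = GroupSummary("a", 2, 0.0, 1.0)
        g2 = GroupSummary("b", 2, 0.0, 3.0)
        assert pooled_sd(g1, g2) == pytest.approx(math.sqrt(5.0), rel=1e-14)


class TestProportion:
    def test_birthweight_proportions(self, birthweight_summaries):
        m = _model(birthweight_summaries["exposed"],
                   birthweight_summaries["reference"])
        thr = birthweight_summaries["threshold"]
        p_smoker = distributional_proportion(m, m.exposed, thr)
        p_non = distributional_proportion(m, m.reference, thr)
        assert p_smoker.p == pytest.approx(0.0396, abs=5e-4)
        assert p_non.p == pytest.approx(0.0147, abs=5e-4)

    def test_mean_at_cutpoint_gives_half(self):
        g1 = GroupSummary("a", 50, 10.0, 2.0)
        g2 = GroupSummary("b", 50, 12.0, 2.0)
        m = _model(g1, g2)
        for tail in ("below", "above"):
            est = distributional_proportion(m, g1, Threshold(10.0, tail))
            assert est.p == pytest.approx(0.5, rel=1e-12)

    def test_closed_form_se(self):
        # mean=0, sd=1, n=100, x0=0: se = phi(0)/sqrt(100)
        g1 = GroupSummary("a", 100, 0.0, 1.0)
        g2 = GroupSummary("b", 100, 0.5, 1.0)
        m = PooledModel(groups=(g1, g2), sd_pooled=1.0)
        est = distributional_proportion(m, g1, Threshold(0.0, "below"))
        assert est.se == pytest.approx(stats.norm.pdf(0.0) / 10.0, rel=1e-12)

    def test_se_shrinks_as_root_n(self):
        thr = Threshold(0.0, "below")
        ses = []
        for n in (100, 400):
            g1 = GroupSummary("a", n, 0.0, 1.0)
            g2 = GroupSummary("b", n, 0.5, 1.0)
            m = PooledModel(groups=(g1, g2), sd_pooled=1.0)
            ses.append(distributional_proportion(m, g1, thr).se)
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=1e-12)

    def test_monte_carlo_validates_delta_method_se(self, rng):
        # SD of the estimate across simulated samples matches the SE.
        # At x0 = mu the proportion is insensitive to the SD estimate
        # (d p / d sigma ~ z*phi(z) = 0), isolating the mean-driven
        # variability the delta method propagates.
        n, reps = 100, 20_000
        x0 = 0.0
        draws = rng.standard_normal((reps, n))
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        p_hat = stats.norm.cdf((x0 - means) / sds)
        g = GroupSummary("a", n, 0.0, 1.0)
        m = PooledModel(groups=(g, GroupSummary("b", n, 0.5, 1.0)), sd_pooled=1.0)
        se = distributional_proportion(m, g, Threshold(x0, "below")).se
        assert p_hat.std(ddof=1) == pytest.approx(se, rel=0.05)

    def test_degenerate_tail_raises(self):
        g1 = GroupSummary("a", 100, 0.0, 1.0)
        g2 = GroupSummary("b", 100, 0.5, 1.0)
        m = PooledModel(groups=(g1, g2), sd_pooled=1.0)
        with pytest.raises(DegenerateTailError):
            distributional_proportion(m, g1, Threshold(-12.0, "below"))


class TestCompareGroups:
    def test_birthweight_printed_values(self, birthweight_summaries):
        m = _model(birthweight_summaries["exposed"],
                   birthweight_summaries["reference"])
        c = compare_groups(m, birthweight_summaries["threshold"])
        assert c.d == pytest.approx(0.025, abs=1e-3)
        assert c.se_d == pytest.approx(0.004, abs=5e-4)
        assert c.ci_d[0] == pytest.approx(0.017, abs=1e-3)
        assert c.ci_d[1] == pytest.approx(0.033, abs=1e-3)
        assert c.rr == pytest.approx(2.68, abs=0.1)
        assert c.or_ == pytest.approx(2.74, abs=0.1)
        assert c.se_log_rr == pytest.approx(0.13, abs=0.01)

    def test_identical_groups_are_null(self):
        g1 = GroupSummary("a", 60, 1.0, 2.0)
        g2 = GroupSummary("b", 60, 1.0, 2.0)
        c = compare_groups(_model(g1, g2), Threshold(0.0, "below"))
        assert c.d == 0.0
        assert c.rr == 1.0
        assert c.or_ == 1.0

    def test_toy_closed_form(self):
        # means 0 and 1, sd 1, x0=0 below: p = 0.5 vs Phi(-1)
        g1 = GroupSummary("a", 100, 0.0, 1.0)
        g2 = GroupSummary("b", 100, 1.0, 1.0)
        c = compare_groups(PooledModel(groups=(g1, g2), sd_pooled=1.0),
                           Threshold(0.0, "below"))
        phi_m1 = stats.norm.cdf(-1.0)
        assert c.d == pytest.approx(0.5 - phi_m1, rel=1e-12)
        assert c.d == pytest.approx(0.3413, abs=1e-4)
        assert c.rr == pytest.approx(0.5 / phi_m1, rel=1e-12)
        assert c.rr == pytest.approx(3.151, abs=1e-3)

    def test_swapping_groups_flips_direction(self, birthweight_summaries):
        m = _model(birthweight_summaries["exposed"],
                   birthweight_summaries["reference"])
        thr = birthweight_summaries["threshold"]
        c = compare_groups(m, thr)
        c_swapped = compare_groups(m.swapped(), thr)
        assert c_swapped.d == pytest.approx(-c.d, rel=1e-12)
        assert c_swapped.rr == pytest.approx(1.0 / c.rr, rel=1e-12)
        assert c_swapped.or_ == pytest.approx(1.0 / c.or_, rel=1e-12)
        assert c_swapped.se_log_rr == pytest.approx(c.se_log_rr, rel=1e-12)
        assert c_swapped.se_log_or == pytest.approx(c.se_log_or, rel=1e-12)

    def test_direction_consistency(self):
        g1 = GroupSummary("a", 100, 1.0, 1.0)
        g2 = GroupSummary("b", 100, 0.0, 1.0)
        c = compare_groups(_model(g1, g2), Threshold(0.5, "above"))
        assert (c.d > 0) and (c.rr > 1) and (c.or_ > 1)

    def test_skew_normal_path_agrees_with_normal_at_alpha_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            mu1, mu2 = rng.uniform(-5, 5, 2)
            sd = rng.uniform(0.2, 4)
            x0 = rng.uniform(-6, 6)
            g1 = GroupSummary("a", 80, mu1, sd)
            g2 = GroupSummary("b", 120, mu2, sd)
            thr = Threshold(x0, "below")
            try:
                c_norm = compare_groups(
                    PooledModel(groups=(g1, g2), sd_pooled=sd), thr)
                c_skew = compare_groups(
                    PooledModel(groups=(g1, g2), sd_pooled=sd, alpha=0.0,
                                method="skew_normal"), thr)
            except DegenerateTailError:
                continue
            assert abs(c_norm.d - c_skew.d) <= 1e-10
            assert abs(c_norm.se_d - c_skew.se_d) <= 1e-10

    def test_duplicate_labels_rejected(self):
        g = GroupSummary("a", 50, 0.0, 1.0)
        with pytest.raises(ConfigError):
            PooledModel(groups=(g, g), sd_pooled=1.0)


class TestDci:
    def test_printed_interval(self):
        lo, hi = dci(0.025, 0.004, 0.95, "identity")
        assert lo == pytest.approx(0.0172, abs=1e-4)
        assert hi == pytest.approx(0.0328, abs=1e-4)

    def test_width_grows_with_level(self):
        w = [dci(0.0, 1.0, lvl)[1] - dci(0.0, 1.0, lvl)[0]
             for lvl in (0.8, 0.95, 0.999)]
        assert w[0] < w[1] < w[2]

    def test_log_scale_interval_contains_unity_for_null_ratio(self):
        lo, hi = dci(1.0, 0.3, 0.95, "log")
        assert lo < 1.0 < hi
        # symmetric on the log scale
        assert math.log(hi) == pytest.approx(-math.log(lo), rel=1e-12)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_level(self, level):
        with pytest.raises(ConfigError):
            dci(0.0, 1.0, level)

    def test_invalid_se(self):
        with pytest.raises(DomainError):
            dci(0.0, 0.0)
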