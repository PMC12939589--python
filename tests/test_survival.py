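import numpy as np
import pytest

from radsurv import (
    compare_strata, greenwood_ci, km_estimate, logrank_test,
)
from radsurv.stratify import BinaryFactor

from oracles import (
    brute_greenwood, brute_km, brute_logrank, permutation_logrank_p,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_mixed_toy_matches_brute_force(self, toy_survival):
        time, event = toy_survival
        curve = km_estimate(time, event)
        ts, surv = brute_km(time, event)
        np.testing.assert_allclose(curve.times, ts)
        np.testing.assert_allclose(curve.survival, surv, atol=1e-15)

    def test_km_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 60)
        curve = km_estimate(t, np.ones(60, int))
        for q in curve.times:
            ecdf = (t <= q).mean()
            assert curve.survival_at(q) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_censored_at_event_time_stays_at_risk(self):
        # censored observation tied at t=2 counts in the t=2 risk set
        curve = km_estimate([1.0, 2.0, 2.0], [1, 1, 0])
        np.testing.assert_allclose(curve.n_risk, [3, 2])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])

    def test_survival_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 100)
        e = (rng.random(100) > 0.3).astype(int)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-15).all()
        assert (np.diff(curve.n_risk) < 0).all()
        assert (curve.n_events <= curve.n_risk).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    def test_median_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert curve.median_survival() == 2.0


class TestGreenwood:
    def test_toy_variance_matches_direct_summation(self, toy_survival):
        time, event = toy_survival
        curve = km_estimate(time, event)
        ts, var = brute_greenwood(time, event)
        np.testing.assert_allclose(curve.greenwood_var, var, atol=1e-12)

    def test_ci_degenerate_where_survival_is_one(self):
        curve = km_estimate([1.0, 2.0], [0, 1])
        lo, hi = greenwood_ci(curve)
        # the single event at t=2 empties the risk set; S=0.5? no: n=1 at t=2
        assert np.all(lo <= hi)
        assert np.all((0 <= lo) & (hi <= 1))

    def test_cumulative_variance_term_monotone(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1, 80)
        e = (rng.random(80) > 0.2).astype(int)
        curve = km_estimate(t, e)
        csum = np.where(curve.survival > 0,
                        curve.greenwood_var / curve.survival**2, np.nan)
        valid = ~np.isnan(csum)
        assert (np.diff(csum[valid]) >= -1e-15).all()

    def test_bands_contain_the_estimate(self, toy_survival):
        curve = km_estimate(*toy_survival)
        lo, hi = greenwood_ci(curve, 0.95)
        inner = curve.survival > 0
        assert np.all(lo[inner] <= curve.survival[inner] + 1e-12)
        assert np.all(curve.survival <= hi + 1e-12)

    def test_invalid_level_rejected(self, toy_survival):
        with pytest.raises(ValueError):
            greenwood_ci(km_estimate(*toy_survival), 1.5)

    def test_survival_one_segment_has_degenerate_band(self):
        from radsurv.survival import KMCurve

        # a curve segment still at S=1 (no events absorbed yet) must carry
        # the degenerate [1, 1] interval
        curve = KMCurve(times=np.array([1.0, 2.0]),
                        n_risk=np.array([5, 4]),
                        n_events=np.array([0, 1]),
                        survival=np.array([1.0, 0.75]),
                        greenwood_var=np.array([0.0, 0.035]), n=5)
        lo, hi = greenwood_ci(curve)
        assert lo[0] == hi[0] == 1.0
        assert lo[1] < 0.75 < hi[1]


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_eight_patient_toy_matches_brute_force(self):
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        g = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(brute_logrank(t, e, g),
                                              abs=1e-12)

    def test_expected_counts_sum_to_observed_events(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 50)
        e = (rng.random(50) > 0.2).astype(int)
        g = rng.choice(["x", "y"], 50)
        res = logrank_test(t, e, g)
        assert sum(res.expected.values()) == pytest.approx(e.sum())
        assert sum(res.observed.values()) == pytest.approx(e.sum())

    def test_analytic_p_close_to_permutation_p(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(1, 16), 2) + 0.01
        e = np.ones(16, int)
        g = np.array(["a"] * 8 + ["b"] * 8)
        t[8:] *= 1.8  # moderate group difference
        res = logrank_test(t, e, g)
        p_perm = permutation_logrank_p(t, e, g, n_perm=10_000, seed=0)
        assert abs(res.p_value - p_perm) < 0.03

    def test_invariant_to_group_relabeling_and_time_transform(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, 40)
        e = (rng.random(40) > 0.25).astype(int)
        g = rng.choice(["a", "b"], 40)
        r1 = logrank_test(t, e, g)
        r2 = logrank_test(np.exp(t), e, g)  # strictly monotone transform
        g_swapped = np.where(g == "a", "b", "a")
        r3 = logrank_test(t, e, g_swapped)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.statistic == pytest.approx(r3.statistic, abs=1e-12)

    def test_doubling_the_sample_doubles_observed_and_expected(self):
        t = np.array([1.0, 2, 3, 5, 8, 9])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a", "b", "a", "b", "a", "b"])
        r1 = logrank_test(t, e, g)
        r2 = logrank_test(np.tile(t, 2), np.tile(e, 2), np.tile(g, 2))
        for k in r1.observed:
            assert r2.observed[k] == pytest.approx(2 * r1.observed[k])
            assert r2.expected[k] == pytest.approx(2 * r1.expected[k])
        assert r2.statistic == pytest.approx(
            brute_logrank(np.tile(t, 2), np.tile(e, 2), np.tile(g, 2)),
            abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(6)
        t = rng.exponential(1, 60)
        e = (rng.random(60) > 0.2).astype(int)
        g = rng.choice(["a", "b"], 60)
        res = logrank_test(t, e, g)
        ref = ll_logrank(t[g == "a"], t[g == "b"],
                         e[g == "a"], e[g == "b"])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_p_display_floor(self):
        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(0.2, 50),
                            rng.exponential(5.0, 50)])
        e = np.ones(100, int)
        g = np.array(["fast"] * 50 + ["slow"] * 50)
        assert logrank_test(t, e, g).display_p() == "<0.0001"


class TestCompareStrata:
    def test_panel_within_restriction(self, default_cohort):
        from radsurv.stratify import binarize_stage, biomarker_factor

        stage = binarize_stage(default_cohort.stage)
        bio = biomarker_factor(default_cohort, "Busyness")
        rec = compare_strata(default_cohort, bio, within=stage.mask("Low"),
                             name="low-stage:biomarker")
        assert rec is not None
        assert set(rec.curves) == {"Low", "High"}
        assert rec.group_stats["n"].sum() == stage.mask("Low").sum()

    def test_empty_side_after_restriction_skipped(self, default_cohort, caplog):
        import logging

        bio = BinaryFactor("const", np.array(["Low"] * default_cohort.n,
                                             dtype=object), ("Low", "High"))
        with caplog.at_level(logging.WARNING):
            rec = compare_strata(default_cohort, bio)
        assert rec is None
        assert "skipped" in caplog.text
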