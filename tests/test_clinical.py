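import numpy as np
import pandas as pd
import pytest

from famnet.clinical import (build_drug_axis, cox_score_test, cox_univariate,
                             drug_correlation, km_estimate, logrank_test,
                             median_split)
from famnet.errors import (DegenerateSplitError, InvalidInputError,
                           UndefinedCorrelationError)
from famnet.synthetic import CohortConfig, generate_cohort


class TestMedianSplit:
    def test_even_split(self):
        groups = median_split([1, 2, 3, 4])
        assert list(groups) == ["low", "low", "high", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(DegenerateSplitError):
            median_split([1, 1, 1, 1])

    def test_ties_at_median_go_low(self):
        groups = median_split([1, 2, 2, 3])
        assert list(groups) == ["low", "low", "low", "high"]

    def test_too_few_samples(self):
        with pytest.raises(InvalidInputError):
            median_split([1, 2, 3])

    def test_empty_high_side_rejected(self):
        with pytest.raises(DegenerateSplitError):
            median_split([1, 3, 3, 3])


class TestKmEstimate:
    def test_three_events_no_censoring(self):
        out = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(out["survival"], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        out = km_estimate([1, 2, 3], [0, 0, 0])
        assert out.empty  # no drops: S identically 1

    def test_risk_set_bookkeeping(self):
        # 4 at risk, event at t=1; censor at 1.5; event at t=2 with 2 at risk
        out = km_estimate([1, 1.5, 2, 3], [1, 0, 1, 0])
        np.testing.assert_allclose(out["survival"], [0.75, 0.375])

    def test_non_positive_time_rejected(self):
        with pytest.raises(InvalidInputError):
            km_estimate([0, 1], [1, 1])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(3)
        out = km_estimate(times, np.ones(40, dtype=int))
        for _, row in out.iterrows():
            empirical = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(10, size=60).round(1) + 0.1
        events = rng.integers(0, 2, size=60)
        out = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in out.iterrows():
            expected = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(expected, abs=1e-12)


class TestLogrankTest:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_four_event_hand_calculation(self):
        # A events at {1,2}, B events at {3,4}: chi2 = 49/17 by 2x2 tables
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-9)

    def test_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(10, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)

    def test_maximal_separation_significant(self, rng):
        res = logrank_test(rng.uniform(1, 2, 10), np.ones(10, int),
                           rng.uniform(1, 2, 10), np.zeros(10, int))
        assert res.chi_square > 0
        assert res.p < 0.05

    def test_zero_events_is_no_test(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(res.chi_square) and np.isnan(res.p)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        ta, tb = rng.exponential(5, 30).round(2) + 0.01, rng.exponential(8, 35).round(2) + 0.01
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 35)
        res = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, ea, eb)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)


class TestCoxUnivariate:
    def test_identical_groups_ns(self, rng):
        t = np.concatenate([rng.exponential(10, 50)] * 2)
        e = np.ones(100, int)
        x = np.concatenate([np.zeros(50), np.ones(50)])
        res = cox_univariate(x, t, e)
        assert abs(res.log_hr) < 0.5
        assert res.direction == "ns"

    def test_no_events_rejected(self):
        with pytest.raises(InvalidInputError):
            cox_univariate([0, 1, 0, 1], [1, 2, 3, 4], [0, 0, 0, 0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(InvalidInputError):
            cox_univariate([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1])

    def test_score_test_equals_logrank_on_untied_data(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 40
            t = r.exponential(10, n)  # continuous: no ties a.s.
            e = r.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            x = r.integers(0, 2, n).astype(float)
            if x.std() == 0:
                x[0] = 1 - x[0]
            chi2, _ = cox_score_test(x, t, e)
            grp = x > 0.5
            lr = logrank_test(t[grp], e[grp], t[~grp], e[~grp])
            if np.isnan(lr.chi_square):
                continue
            assert chi2 == pytest.approx(lr.chi_square, abs=1e-6)

    def test_matches_lifelines_on_untied_data(self, rng):
        from lifelines import CoxPHFitter
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 / (1 + x), n)
        e = (t < rng.uniform(0, 30, n)).astype(int)
        res = cox_univariate(x, t, e)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_efron_matches_breslow_without_ties(self, rng):
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10, n)
        e = np.ones(n, int)
        res_b = cox_univariate(x, t, e, ties="breslow")
        res_e = cox_univariate(x, t, e, ties="efron")
        assert res_b.log_hr == pytest.approx(res_e.log_hr, abs=1e-9)

    def test_recovers_generator_log_hr(self):
        # parameter recovery on generator output, ln 2 true effect
        true = float(np.log(2))
        cfg = CohortConfig(seed=77, n_cancer=500, n_normal=10,
                           survival_gene="FAM001", survival_log_hr=true)
        cohort = generate_cohort(cfg)
        values = cohort.expression_cancer.loc["FAM001"].to_numpy()
        high = (values > np.median(values)).astype(float)
        res = cox_univariate(high, cohort.survival["time"],
                             cohort.survival["event"])
        assert abs(res.log_hr - true) < 3 * res.se

    def test_complete_separation_flagged(self):
        # group 1 all events early, group 0 all censored late
        t = np.array([1, 2, 3, 4, 50, 60, 70, 80], dtype=float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = cox_univariate(x, t, e)
        assert res.separation
        assert res.ci_high == np.inf


class TestDrugCorrelation:
    def test_retained(self, rng):
        x = rng.normal(size=50)
        y = 0.7 * x + 0.3 * rng.normal(size=50)
        res = drug_correlation(x, y)
        assert res.retained

    def test_magnitude_gate(self, rng):
        # tiny |pcc| with huge n would be significant but must be dropped
        x = rng.normal(size=10000)
        y = 0.1 * x + rng.normal(size=10000)
        res = drug_correlation(x, y)
        if abs(res.pcc) <= 0.2:
            assert not res.retained

    def test_p_gate(self):
        # |pcc| = 0.5 clears the magnitude gate but p = 0.667 at n = 3
        res = drug_correlation([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert res.pcc == pytest.approx(0.5)
        assert not res.retained

    def test_threshold_is_strict(self, rng):
        # r pinned to exactly 0.2 via Gram-Schmidt (n small enough that the
        # p gate also fails, avoiding float tie-breaking at the boundary)
        x = rng.normal(size=50)
        w = rng.normal(size=50)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        wc = w - w.mean()
        wc -= (wc @ xc) * xc
        wc /= np.linalg.norm(wc)
        y = 0.2 * xc + np.sqrt(1 - 0.04) * wc  # r(x, y) = 0.2 exactly
        res = drug_correlation(x, y)
        assert res.pcc == pytest.approx(0.2, abs=1e-12)
        assert not res.retained

    def test_series_aligned_on_index(self, rng):
        expr = pd.Series(rng.normal(size=6), index=list("abcdef"))
        ic50 = pd.Series(expr[["a", "b", "c", "d"]].to_numpy(),
                         index=["a", "b", "c", "d"])
        res = drug_correlation(expr, ic50)
        assert res.n == 4
        assert res.pcc == pytest.approx(1.0)

    def test_too_few_lines_rejected(self):
        with pytest.raises(InvalidInputError):
            drug_correlation([1, 2], [3, 4])

    def test_filter_conserves_counts(self, rng):
        results = [drug_correlation(rng.normal(size=20), rng.normal(size=20))
                   for _ in range(50)]
        retained = sum(r.retained for r in results)
        dropped = sum(not r.retained for r in results)
        assert retained + dropped == 50


class TestBuildDrugAxis:
    @staticmethod
    def _gd(rows):
        return pd.DataFrame(rows, columns=["gene", "drug", "retained"])

    @staticmethod
    def _gt(rows):
        return pd.DataFrame(rows, columns=["gene", "target", "retained"])

    @staticmethod
    def _anno(rows):
        return pd.DataFrame(rows, columns=["drug", "target_gene", "pathway"])

    def test_empty(self):
        out = build_drug_axis(self._gd([]), self._gt([]), self._anno([]))
        assert out.empty

    def test_single_row_join(self):
        out = build_drug_axis(self._gd([("G", "D", True)]),
                              self._gt([("G", "T", True)]),
                              self._anno([("D", "T", "P")]))
        assert len(out) == 1
        assert tuple(out.iloc[0]) == ("P", "D", "G", "T")

    def test_join_multiplicity(self):
        out = build_drug_axis(
            self._gd([("G", "D", True)]),
            self._gt([("G", "T1", True), ("G", "T2", True)]),
            self._anno([("D", "T1", "P1"), ("D", "T2", "P2")]))
        assert len(out) == 2

    def test_unretained_and_unannotated_dropped(self):
        out = build_drug_axis(
            self._gd([("G", "D", False), ("G", "D2", True)]),
            self._gt([("G", "T", True)]),
            self._anno([("D", "T", "P")]))
        assert out.empty
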