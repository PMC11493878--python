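"""Group comparisons, Holm correction, architecture contrasts, regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaslab import stats
from plaslab.stats import (holm_bonferroni, ols_fit, one_sample_t,
                           response_regression, sleep_architecture_contrasts,
                           two_sample_t, two_sample_t_from_summary, yates_chi2)

finite_floats = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestTwoSampleT:
    def test_published_group_comparisons(self):
        # cognitive screening score: healthy 27.94±1.43 (18) vs 23.25±1.57 (16)
        res = two_sample_t_from_summary(27.94, 1.43, 18, 23.25, 1.57, 16)
        assert res.df == 32
        assert res.t == pytest.approx(9.112, rel=0.01)
        # age 68.33±5.13 vs 71.94±3.99
        res = two_sample_t_from_summary(68.33, 5.13, 18, 71.94, 3.99, 16)
        assert res.t == pytest.approx(-2.264, rel=0.01)
        # baseline memory 13.11±4.43 vs 9.38±4.70
        res = two_sample_t_from_summary(13.11, 4.43, 18, 9.38, 4.70, 16)
        assert res.t == pytest.approx(2.37, rel=0.01)

    def test_identical_summaries_null(self):
        res = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_raw(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(finite_floats, min_size=3, max_size=12),
           st.lists(finite_floats, min_size=3, max_size=12))
    def test_raw_equals_summary(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            return
        raw = two_sample_t(x, y)
        summ = two_sample_t_from_summary(x.mean(), x.std(ddof=1), len(x),
                                         y.mean(), y.std(ddof=1), len(y))
        assert raw.t == pytest.approx(summ.t, rel=1e-10, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-10, abs=1e-12)


class TestYatesChi2:
    def test_published_gender_table(self):
        res = yates_chi2([[4, 14], [10, 6]])
        assert res.chi2 == pytest.approx(4.13, rel=0.01)
        assert res.df == 1
        assert res.p == pytest.approx(0.042, abs=0.002)

    def test_independence_zero(self):
        assert yates_chi2([[5, 5], [5, 5]]).chi2 == 0.0

    def test_hand_corrected_value(self):
        assert yates_chi2([[10, 0], [0, 10]]).chi2 == pytest.approx(16.2)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            yates_chi2([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            yates_chi2([[1, 2, 3], [4, 5, 6]])


class TestHolmBonferroni:
    def test_textbook_cases(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.1, 1.3])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=10))
    def test_adjustment_properties(self, p):
        adj = holm_bonferroni(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # monotone in the order statistics
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSleepArchitecture:
    # group-mean sleep-architecture values per night (minutes / %), as used
    # in the published difference-score procedure
    HC_NIGHTS = {"BL": {"N3": 38.444}, "E1": {"N3": 32.333},
                 "E2": {"N3": 40.583}, "E3": {"N3": 40.611}}

    def _table(self, per_night_by_group, n_per_group=4, jitter=0.0):
        rows = []
        for group, nights in per_night_by_group.items():
            for i in range(n_per_group):
                for night, params in nights.items():
                    row = {"participant_id": f"{group}{i}", "group": group,
                           "night": night}
                    for k, v in params.items():
                        row[k] = v + jitter * (i - (n_per_group - 1) / 2)
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_identical_nights_no_rejections(self):
        nights = {n: {"N3": 30.0, "REM": 50.0} for n in ("BL", "E1", "E2", "E3")}
        out = sleep_architecture_contrasts(
            self._table({"HC": nights, "CI": nights}))
        assert (out["difference_scores"][["N3", "REM"]] == 0).all().all()
        for res in out["between"].values():
            assert res.p_adjusted == 1.0
        for g in out["within"].values():
            for res in g.values():
                assert res.p_adjusted == 1.0

    def test_published_mean_difference_score(self):
        # (32.333 + 40.583 + 40.611)/3 - 38.444 = -0.602 min of N3
        out = sleep_architecture_contrasts(
            self._table({"HC": self.HC_NIGHTS}, jitter=0.01))
        assert out["difference_scores"]["N3"].mean() == pytest.approx(-0.602,
                                                                      abs=0.001)

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for group, shift in (("HC", 0.0), ("CI", 20.0)):
            for i in range(8):
                for night in ("BL", "E1", "E2", "E3"):
                    n3 = 35.0 + rng.normal(0, 3.0)
                    if night != "BL":
                        n3 += shift
                    rows.append({"participant_id": f"{group}{i}",
                                 "group": group, "night": night, "N3": n3})
        out = sleep_architecture_contrasts(pd.DataFrame(rows))
        assert out["between"]["N3"].p_adjusted < 0.05

    def test_incomplete_participants_excluded(self):
        nights = {n: {"N3": 30.0} for n in ("BL", "E1", "E2", "E3")}
        table = self._table({"HC": nights, "CI": nights}, jitter=0.1)
        table = table[~((table["participant_id"] == "HC0")
                        & (table["night"] == "E2"))]
        out = sleep_architecture_contrasts(table)
        assert out["excluded_participants"] == ["HC0"]
        assert "HC0" not in out["difference_scores"].index


class TestRegressions:
    def test_exact_linear_fit(self):
        x = np.arange(10, dtype=float)
        fit = ols_fit(2.0 * x, {"x": x})
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_null_relation_calibrated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        fit = ols_fit(y, {"x": x})
        assert abs(fit.adj_r2) < 0.05
        assert 0.0 < fit.p <= 1.0

    def test_rank_deficient_named(self):
        with pytest.raises(ValueError, match="pre"):
            ols_fit(np.arange(8.0), {"pre": np.ones(8)})

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            ols_fit(np.arange(3.0), {"x": np.arange(3.0)})

    def test_response_regression_with_covariates(self):
        rng = np.random.default_rng(2)
        n = 30
        table = pd.DataFrame({
            "group": ["CI"] * n,
            "gender": rng.choice(["M", "F"], n),
            "age": rng.normal(70, 4, n),
            "response_score_erp": rng.normal(5, 2, n),
        })
        table["abeta_diff"] = 0.001 * table["response_score_erp"] + \
            rng.normal(0, 0.002, n)
        fit = response_regression(table, "abeta_diff", subset="CI",
                                  covariates=["age", "gender"])
        assert fit.covariate_model is not None
        assert fit.df == (1, n - 2)
        assert fit.covariate_model.df == (3, n - 4)
        se = abs(fit.coefficients["response_score_erp"]) / np.sqrt(fit.F)
        assert abs(fit.coefficients["response_score_erp"] - 0.001) < 3 * se

    def test_baseline_independence_check(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "group": ["HC"] * 20 + ["CI"] * 20,
            "abeta_pre": rng.normal(0.07, 0.008, 40),
            "response_score_erp": rng.normal(5, 2, 40),
        })
        out = stats.baseline_independence_check(table)
        assert set(out) == {"HC", "CI"}
        for fit in out.values():
            assert fit.p > 0.01   # independent by construction (seeded)

    def test_baseline_independence_degenerate(self):
        table = pd.DataFrame({"group": ["CI"] * 10,
                              "abeta_pre": np.full(10, 0.07),
                              "response_score_erp": np.arange(10.0)})
        with pytest.raises(ValueError):
            stats.baseline_independence_check(table)
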