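"""Median splits, chi-square, group tests, logistic fits, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycoprog import (SeparationError, chi_square_2x2, fit_logistic,
                       group_tests, median_split, model_suite,
                       stratified_incidence, trajectory_summary)
from glycoprog.synthetic_cohort import build_table2_fixture


class TestMedianSplit:
    def test_even_split(self):
        assert list(median_split([1, 2, 3, 4])) == ["LOW", "LOW", "HIGH", "HIGH"]

    def test_odd_n_median_element_goes_low(self):
        assert list(median_split([1, 2, 3])) == ["LOW", "LOW", "HIGH"]

    def test_degenerate_all_identical_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = median_split([5, 5, 5])
        assert list(labels) == ["LOW", "LOW", "LOW"]

    def test_custom_labels_and_nan_passthrough(self):
        labels = median_split([1.0, np.nan, 10.0], high_label="LARGE",
                              low_label="SMALL")
        assert list(labels) == ["SMALL", None, "LARGE"]

    def test_too_few_defined(self):
        with pytest.raises(ValueError):
            median_split([1.0, np.nan])


class TestChiSquare2x2:
    def test_independence_gives_zero(self):
        res = chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_published_low_bcf_t2d_cell(self):
        res = chi_square_2x2(45, 658, 18, 684)
        assert res.statistic == pytest.approx(12.07, abs=0.01)
        assert res.p_value < 0.001

    def test_zero_margin_flagged(self):
        res = chi_square_2x2(0, 0, 5, 5)
        assert not res.valid and res.statistic is None

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            chi_square_2x2(-1, 2, 3, 4)

    def test_agrees_with_expected_count_formulation(self, rng):
        """Brute-force sum (O-E)^2/E over cells equals the closed form."""
        for _ in range(100):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = chi_square_2x2(a, b, c, d)
            obs = np.array([[a, b], [c, d]], dtype=float)
            n = obs.sum()
            exp = np.outer(obs.sum(1), obs.sum(0)) / n
            brute = ((obs - exp) ** 2 / exp).sum()
            assert res.statistic == pytest.approx(brute, abs=1e-10)
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
            assert res.statistic == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-12)


class TestStratifiedIncidence:
    def test_fixture_reproduces_published_cells(self):
        table = stratified_incidence(build_table2_fixture())
        assert table.counts.loc["T2D_P", ("LOW", "LARGE")] == 45
        assert table.counts.loc["NON_P", ("LOW", "SMALL")] == 447
        assert table.percentages.loc["T2D_P", ("LOW", "LARGE")] == pytest.approx(6.4, abs=0.05)
        assert table.percentages.loc["NON_P", ("LOW", "SMALL")] == pytest.approx(63.7, abs=0.05)
        assert table.total_n == 2810

    def test_counts_sum_to_cohort_size(self):
        df = pd.DataFrame({
            "bcf_stratum": ["LOW", "LOW", "HIGH"],
            "dis_stratum": ["LARGE", "SMALL", "LARGE"],
            "progression": ["T2D_P", "NON_P", "PREDM_P"]})
        table = stratified_incidence(df)
        assert table.total_n == 3

    def test_single_participant_cell_is_100_percent(self):
        df = pd.DataFrame({"bcf_stratum": ["LOW"], "dis_stratum": ["LARGE"],
                           "progression": ["NON_P"]})
        table = stratified_incidence(df)
        assert table.percentages.loc["NON_P", ("LOW", "LARGE")] == pytest.approx(100.0)
        assert np.isnan(table.percentages[("HIGH", "SMALL")]).all()


class TestGroupTests:
    def test_identical_groups_t_zero(self):
        rep = group_tests({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert rep.test == "t"
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_pooled_variance_t_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        rep = group_tests({"a": a, "b": b})
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert rep.statistic == pytest.approx(float(t), rel=1e-12)

    def test_three_groups_equal_means_f_zero(self):
        rep = group_tests({"a": [-1.0, 0, 1], "b": [-2.0, 0, 2], "c": [-3.0, 0, 3]})
        assert rep.test == "anova"
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_bonferroni_factor_is_number_of_pairs(self, rng):
        groups = {k: rng.normal(size=10) for k in "abc"}
        rep = group_tests(groups)
        assert len(rep.pairwise) == 3
        for pw in rep.pairwise:
            assert pw.p_adjusted == pytest.approx(min(1.0, pw.p_raw * 3))

    def test_small_group_is_error(self):
        with pytest.raises(ValueError, match="n < 2"):
            group_tests({"a": [1.0], "b": [1.0, 2.0]})


class TestFitLogistic:
    def test_saturated_2x2_equals_closed_form_log_odds_ratio(self):
        # 45 events among 703 exposed, 18 among 702 unexposed
        y = np.r_[np.ones(45), np.zeros(658), np.ones(18), np.zeros(684)]
        x = pd.DataFrame({"exposed": np.r_[np.ones(703), np.zeros(702)]})
        fit = fit_logistic(y, x)
        expected = np.log((45 * 684) / (658 * 18))
        assert fit.params["exposed"] == pytest.approx(expected, abs=1e-8)
        assert fit.odds_ratios["exposed"] == pytest.approx(np.exp(expected), rel=1e-8)

    def test_null_covariate_slope_near_zero(self, rng):
        n = 4000
        x = pd.DataFrame({"z": rng.normal(size=n)})
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_logistic(y, x)
        assert abs(fit.params["z"]) < 0.12  # ~3 SE at this n

    def test_duplicate_column_is_rank_error(self):
        x = pd.DataFrame({"a": [0.0, 1, 0, 1], "b": [0.0, 1, 0, 1]})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(np.array([0, 1, 0, 1.0]), x)

    def test_perfect_separation_detected(self):
        x = pd.DataFrame({"z": np.r_[np.linspace(-2, -0.1, 20),
                                     np.linspace(0.1, 2, 20)]})
        y = (x["z"] > 0).astype(float).to_numpy()
        with pytest.raises(SeparationError):
            fit_logistic(y, x)

    def test_standardization_is_reparameterization(self, rng):
        n = 500
        x = pd.DataFrame({"u": rng.normal(2, 3, n), "v": rng.normal(size=n),
                          "bin": rng.integers(0, 2, n).astype(float)})
        eta = 0.4 * x["u"] - 0.3 * x["v"] + 0.5 * x["bin"] - 1
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, x, standardize=True)
        assert fit.std_deviance == pytest.approx(fit.deviance, abs=1e-6)
        # standardized slope = unstandardized slope * SD for continuous terms
        assert fit.std_params["u"] == pytest.approx(
            fit.params["u"] * x["u"].std(ddof=1), rel=1e-6)
        # binary covariate untouched
        assert fit.std_params["bin"] == pytest.approx(fit.params["bin"], rel=1e-6)

    def test_degenerate_outcome_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(np.zeros(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestModelSuite:
    @staticmethod
    def _make_data(rng, n=1200, beta_dis=1.0, beta_dbcf=0.5):
        dis = rng.normal(0.4, 0.5, n)
        dbcf = rng.normal(0.08, 0.2, n)
        eta = -1.5 + beta_dis * dis + beta_dbcf * dbcf
        predm = rng.random(n) < 1 / (1 + np.exp(-eta))
        prog = np.where(predm, "PREDM_P", "NON_P")
        prog[rng.random(n) < 0.04] = "T2D_P"
        return pd.DataFrame({
            "dis": dis, "dbcf": dbcf, "sex_male": rng.integers(0, 2, n),
            "age": rng.normal(50, 8, n), "bmi": rng.normal(24, 3, n),
            "baseline_is_high": rng.integers(0, 2, n),
            "baseline_bcf_high": rng.integers(0, 2, n),
            "progression": prog})

    def test_fits_six_models_with_ratios(self, rng):
        fits = model_suite(self._make_data(rng))
        assert len(fits) == 6
        assert {(f.outcome, f.model_id) for f in fits} == {
            (o, m) for o in ("preDM", "DM") for m in (1, 2, 3)}
        for f in fits:
            assert f.ratio_standardized is not None
            assert np.isfinite(f.params).all()

    def test_adjusting_for_independent_covariates_preserves_dis_effect(self, rng):
        data = self._make_data(rng, n=8000)
        fits = {f.model_id: f for f in model_suite(data) if f.outcome == "preDM"}
        assert fits[1].params["dis"] == pytest.approx(fits[2].params["dis"], abs=0.12)

    def test_degenerate_categorical_dropped_with_warning(self, rng):
        data = self._make_data(rng)
        data["baseline_is_high"] = 0
        with pytest.warns(UserWarning, match="degenerate"):
            fits = model_suite(data)
        m3 = [f for f in fits if f.model_id == 3][0]
        assert "baseline_is_high" in m3.dropped_columns
        assert "baseline_is_high" not in m3.params.index


class TestTrajectorySummary:
    def test_constant_trajectories_no_decline(self):
        df = pd.DataFrame({
            "id": ["A"] * 3 + ["B"] * 3,
            "progression": ["NON_P"] * 6,
            "visit_index": [0, 2, 5, 0, 2, 5],
            "matsuda": [8.0, 8.0, 8.0, 12.0, 12.0, 12.0]})
        out = trajectory_summary(df, "matsuda")
        assert (out["pct_decline_from_baseline"].abs() < 1e-12).all()
        assert not out["significant_vs_baseline"].any()

    def test_single_visit_cohort_baseline_only(self):
        df = pd.DataFrame({"id": ["A", "B"], "progression": ["NON_P"] * 2,
                           "visit_index": [0, 0], "matsuda": [8.0, 10.0]})
        out = trajectory_summary(df, "matsuda")
        assert len(out) == 1 and out.visit_index[0] == 0

    def test_programmed_decline_recovered(self, rng):
        n = 400
        base = rng.uniform(6, 14, n)
        df = pd.concat([
            pd.DataFrame({"id": np.arange(n), "progression": "NON_P",
                          "visit_index": 0, "matsuda": base}),
            pd.DataFrame({"id": np.arange(n), "progression": "NON_P",
                          "visit_index": 5,
                          "matsuda": base * 0.7 * rng.normal(1, 0.05, n)}),
        ])
        out = trajectory_summary(df, "matsuda")
        year10 = out[out.visit_index == 5].iloc[0]
        assert year10["pct_decline_from_baseline"] == pytest.approx(30.0, abs=1.5)
        assert year10["significant_vs_baseline"]
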