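import numpy as np
import pandas as pd
import pytest

from ankle_ssm import (
    ClusterLogit,
    SeparationError,
    cluster_robust_covariance,
    fit_logistic_irls,
    odds_ratio_table,
    run_injury_models,
    run_race_model,
    simulate_cohort,
)
from conftest import small_spec
from helpers import logistic_mle_oracle, truth_mode_scores


def two_by_two_design():
    """Exposed: 8 events / 2 non-events; unexposed: 4 events / 6 non-events."""
    x = np.array([1] * 10 + [0] * 10, dtype=float)
    y = np.array([1] * 8 + [0] * 2 + [1] * 4 + [0] * 6, dtype=float)
    X = np.column_stack([np.ones(20), x])
    return X, y


class TestIrls:
    def test_saturated_2x2_slope_is_log_cross_product_ratio(self):
        X, y = two_by_two_design()
        fit = fit_logistic_irls(X, y)
        assert fit.coef[1] == pytest.approx(np.log(6.0), abs=1e-8)

    def test_balanced_design_slope_exactly_zero(self):
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_logistic_irls(X, y)
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_newton_oracle_on_20_random_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(20, 51))
            p = int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
            beta = rng.uniform(-1, 1, p + 1)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
            if len(np.unique(y)) < 2:
                continue
            try:
                fit = fit_logistic_irls(X, y)
            except SeparationError:
                continue
            oracle = logistic_mle_oracle(X, y)
            assert np.abs(fit.coef - oracle).max() <= 1e-8

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(120), rng.standard_normal((120, 3))])
        y = (rng.random(120) < 1 / (1 + np.exp(-X[:, 1] + 0.5 * X[:, 2]))).astype(float)
        fit = fit_logistic_irls(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_naive)), ref.bse,
                                   atol=1e-6)

    def test_gradient_vanishes_and_probabilities_in_open_interval(self):
        X, y = two_by_two_design()
        fit = fit_logistic_irls(X, y)
        mu = fit.fitted
        grad = X.T @ (y - mu)
        assert np.abs(grad).max() <= 1e-6
        assert np.all((mu > 0) & (mu < 1))

    def test_constant_outcome_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError, match="constant"):
            fit_logistic_irls(X, np.ones(10))

    def test_complete_separation_detected(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        X = np.column_stack([np.ones(20), x])
        with pytest.raises(SeparationError):
            fit_logistic_irls(X, y)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), a, 2 * a])
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic_irls(X, y, names=["const", "a", "a_twice"])


class TestClusterCovariance:
    @pytest.fixture()
    def fit(self):
        rng = np.random.default_rng(11)
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        return fit_logistic_irls(X, y)

    def test_singleton_clusters_reduce_to_hc0_times_small_sample_factor(self, fit):
        n = fit.n_obs
        cov = cluster_robust_covariance(fit, np.arange(n))
        resid = fit.y - fit.fitted
        meat = (fit.X * resid[:, None]).T @ (fit.X * resid[:, None])
        hc0 = fit.cov_naive @ meat @ fit.cov_naive
        np.testing.assert_allclose(cov, hc0 * n / (n - 1), atol=1e-10)

    def test_invariant_to_relabeling_and_row_order(self, fit):
        n = fit.n_obs
        groups = np.repeat(np.arange(n // 2), 2)
        cov = cluster_robust_covariance(fit, groups)
        relabeled = np.array([f"g{g + 1000}" for g in groups])
        np.testing.assert_allclose(
            cluster_robust_covariance(fit, relabeled), cov, atol=1e-14
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        refit = fit_logistic_irls(fit.X[perm], fit.y[perm])
        cov_perm = cluster_robust_covariance(refit, groups[perm])
        np.testing.assert_allclose(cov_perm, cov, atol=1e-8)

    def test_matches_statsmodels_cluster_covariance(self, fit):
        import statsmodels.api as sm

        n, p = fit.X.shape
        groups = np.repeat(np.arange(n // 4), 4)
        cov = cluster_robust_covariance(fit, groups)
        ref = sm.Logit(fit.y, fit.X).fit(
            disp=0, cov_type="cluster", cov_kwds={"groups": groups}
        )
        # statsmodels applies an extra (n-1)/(n-p) degrees-of-freedom factor
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov)) * np.sqrt((n - 1) / (n - p)), ref.bse, atol=1e-8
        )

    def test_independent_rows_robust_close_to_naive(self):
        # correctly specified independent data: both estimators consistent
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(20):
            n = 2000
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = (rng.random(n) < 1 / (1 + np.exp(-0.2 - 0.5 * X[:, 1]))).astype(float)
            f = fit_logistic_irls(X, y)
            cov = cluster_robust_covariance(f, np.arange(n))
            ratios.append(np.sqrt(np.diag(cov)) / np.sqrt(np.diag(f.cov_naive)))
        assert np.abs(np.mean(ratios, axis=0) - 1.0).max() < 0.15

    def test_single_cluster_rejected(self, fit):
        with pytest.raises(ValueError):
            cluster_robust_covariance(fit, np.zeros(fit.n_obs))


class TestOddsRatioTable:
    def _fit(self, beta, se):
        X, y = two_by_two_design()
        fit = fit_logistic_irls(X, y)
        fit.coef = np.array([0.0, beta])
        cov = np.diag([0.1, se**2])
        return fit, cov

    def test_null_beta_interval_arithmetic(self):
        fit, cov = self._fit(0.0, 0.5)
        tab = odds_ratio_table(fit, cov)
        row = tab.iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.ci_lower == pytest.approx(np.exp(-1.96 * 0.5), rel=1e-6)
        assert row.ci_upper == pytest.approx(np.exp(+1.96 * 0.5), rel=1e-6)
        assert not row.significant

    def test_reference_row_transform(self):
        # inverting a printed OR row: beta=1.1346, SE=0.457
        fit, cov = self._fit(1.1346, 0.457)
        row = odds_ratio_table(fit, cov).iloc[0]
        assert row.odds_ratio == pytest.approx(3.11, abs=0.005)
        assert row.ci_lower == pytest.approx(1.27, abs=0.01)
        assert row.ci_upper == pytest.approx(7.65, abs=0.05)
        assert row.significant

    def test_ci_contains_or_and_widens_with_se(self):
        widths = []
        for se in (0.1, 0.3, 0.6, 1.0):
            fit, cov = self._fit(0.4, se)
            row = odds_ratio_table(fit, cov).iloc[0]
            assert row.ci_lower < row.odds_ratio < row.ci_upper
            widths.append(row.ci_upper - row.ci_lower)
        assert all(np.diff(widths) > 0)

    def test_intercept_excluded(self):
        fit, cov = self._fit(0.4, 0.3)
        fit.names = ["const", "exposure"]
        tab = odds_ratio_table(fit, cov)
        assert list(tab.predictor) == ["exposure"]

    def test_bad_covariance_diagonal_rejected(self):
        fit, _ = self._fit(0.4, 0.3)
        with pytest.raises(ValueError):
            odds_ratio_table(fit, np.diag([1.0, -0.1]))


class TestStudyModels:
    def test_minimal_and_adjusted_tables_have_expected_rows(self, cohort):
        dataset, truth = cohort
        or1, or2 = run_injury_models(truth_mode_scores(truth),
                                     dataset.metadata_frame())
        n_modes = truth.scores.shape[1]
        assert len(or1) == n_modes
        assert len(or2) == n_modes + 6  # six adjustment covariates
        assert {"age", "bmi", "race", "sex", "klg", "symptoms"} <= set(or2.predictor)

    def test_race_model_row_count_equals_mode_count(self, cohort):
        dataset, truth = cohort
        tab = run_race_model(truth_mode_scores(truth), dataset.metadata_frame())
        assert len(tab) == truth.scores.shape[1]

    def test_race_shift_detected_with_high_power(self):
        hits = 0
        reps = 100
        for rep in range(reps):
            spec = small_spec(3000 + rep, n_participants=273,
                              race_mode1_shift=0.8)
            dataset, truth = simulate_cohort(spec)
            tab = run_race_model(truth_mode_scores(truth),
                                 dataset.metadata_frame())
            row = tab.set_index("predictor").loc["mode1"]
            hits += int(row.ci_lower > 1.0)
        assert hits / reps >= 0.90

    def test_null_generator_type_i_error_near_nominal(self):
        # no effects anywhere: pooled fraction of mode CIs excluding 1
        excl = []
        for rep in range(150):
            spec = small_spec(5000 + rep, n_participants=150)
            dataset, truth = simulate_cohort(spec)
            or1, _ = run_injury_models(truth_mode_scores(truth),
                                       dataset.metadata_frame())
            excl.extend((~((or1.ci_lower <= 1.0) & (or1.ci_upper >= 1.0))).tolist())
        assert np.mean(excl) == pytest.approx(0.05, abs=0.03)

    def test_misaligned_scores_metadata_rejected(self, cohort):
        dataset, truth = cohort
        with pytest.raises(ValueError):
            run_race_model(truth_mode_scores(truth),
                           dataset.metadata_frame().iloc[:-2])


class TestClusterLogitInterface:
    def test_results_summary_and_frames(self, cohort):
        dataset, truth = cohort
        df = pd.concat(
            [truth_mode_scores(truth).frame().reset_index(drop=True),
             dataset.metadata_frame().reset_index(drop=True)],
            axis=1,
        )
        res = ClusterLogit.from_dataframe(
            df, "injury", ["mode1", "mode2"], groups="participant_id"
        ).fit()
        tab = res.summary()
        assert list(tab.predictor) == ["mode1", "mode2"]
        assert res.params.index[0] == "const"
        ci = res.conf_int()
        assert (ci["lower"] < ci["upper"]).all()
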