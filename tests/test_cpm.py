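import numpy as np
import pandas as pd
import pytest

from connpredict import cpm
from connpredict.cpm import (
    ModelConfig,
    build_covariates,
    external_validation,
    fit_model,
    fit_second_stage,
    loo_cv,
    predict,
    select_features,
    strength,
)


def make_cohort_frame(y, age=None, sex=None, baseline=None, scanner=None):
    n = len(y)
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": age if age is not None else rng.uniform(8, 17, n),
            "sex": sex if sex is not None else rng.integers(0, 2, n),
            "scanner": scanner if scanner is not None else np.zeros(n, int),
            "pars_baseline": baseline if baseline is not None else rng.uniform(9, 25, n),
            "pars_post": y,
        }
    )


class TestSelectFeatures:
    def test_exact_feature_selected_positive(self, rng):
        X = rng.standard_normal((30, 15))
        y = X[:, 4].copy()
        pos, neg, r = select_features(X, y, None, ModelConfig())
        assert 4 in pos
        assert neg.size == 0 or 4 not in neg
        assert r[4] == pytest.approx(1.0)

    def test_negative_association_lands_in_negative_set(self, rng):
        X = rng.standard_normal((30, 10))
        y = -X[:, 2] + 0.01 * rng.standard_normal(30)
        pos, neg, _ = select_features(X, y, None, ModelConfig())
        assert 2 in neg and 2 not in pos

    def test_type_one_rate_near_alpha_under_null(self):
        rng = np.random.default_rng(21)
        rates = []
        for _ in range(40):
            X = rng.standard_normal((60, 500))
            y = rng.standard_normal(60)
            pos, neg, _ = select_features(X, y, None, ModelConfig(alpha_select=0.01))
            rates.append((pos.size + neg.size) / 500)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 0.01) < 3 * se + 1e-3

    def test_planted_edges_recovered(self, planted_cohort):
        c = planted_cohort
        in_a = c.dataset("A")
        X = c.edges_session1.matrix[in_a]
        y = c.phenotypes.loc[in_a, "pars_post"].to_numpy()
        pos, neg, _ = select_features(X, y, None, ModelConfig())
        recall = len(set(c.signal_edge_idx) & set(pos)) / len(c.signal_edge_idx)
        assert recall >= 0.8

    def test_matches_statsmodels_per_feature_regression(self, rng):
        # independent oracle: per-feature OLS with covariates via statsmodels
        import statsmodels.api as sm

        X = rng.standard_normal((35, 8))
        C = rng.standard_normal((35, 2))
        y = X[:, 1] * 0.8 + C[:, 0] * 0.5 + rng.standard_normal(35)
        config = ModelConfig(covariate_mode="predictors", covariates=("a", "b"))
        pos, neg, r = select_features(X, y, C, config)
        for j in range(8):
            design = sm.add_constant(np.column_stack([C, X[:, j]]))
            p_sm = sm.OLS(y, design).fit().pvalues[-1]
            selected = j in pos or j in neg
            assert selected == (p_sm < 0.01)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="10 training subjects"):
            select_features(rng.standard_normal((9, 5)),
                            rng.standard_normal(9), None, ModelConfig())


class TestStrength:
    def test_sum_of_selected_values(self):
        row = np.array([0.3, 0.5, -0.2])
        s = strength(row, np.array([0, 1]), np.array([], int), ModelConfig())
        assert s[0, 0] == pytest.approx(0.8)

    def test_all_zero_values_give_zero(self):
        s = strength(np.zeros(4), np.array([1, 2]), np.array([], int), ModelConfig())
        assert s[0, 0] == 0.0

    def test_correlation_weighted_hand_value(self):
        # edges z = 0.3, 0.5 with weights 0.2, 0.4: 0.3*0.2 + 0.5*0.4 = 0.26
        row = np.array([0.3, 0.5])
        w = np.array([0.2, 0.4])
        cfg = ModelConfig(weighting="correlation")
        s = strength(row, np.array([0, 1]), np.array([], int), cfg, weights=w)
        assert s[0, 0] == pytest.approx(0.26)

    def test_both_mode_two_columns(self, rng):
        row = rng.standard_normal(6)
        cfg = ModelConfig(selection="both")
        s = strength(row, np.array([0, 1]), np.array([2]), cfg)
        assert s.shape == (1, 2)
        assert s[0, 0] == pytest.approx(row[:2].sum())
        assert s[0, 1] == pytest.approx(row[2])

    def test_both_as_difference(self, rng):
        row = rng.standard_normal(6)
        cfg = ModelConfig(selection="both", both_as_difference=True)
        s = strength(row, np.array([0]), np.array([1]), cfg)
        assert s[0, 0] == pytest.approx(row[0] - row[1])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            strength(np.zeros(3), np.array([5]), np.array([], int), ModelConfig())


class TestSecondStage:
    def test_noise_free_coefficients_recovered(self, rng):
        S = rng.standard_normal((40, 1))
        y = 3.0 + 2.5 * S[:, 0]
        fit = fit_second_stage(S, y, None, ModelConfig())
        assert fit.second_stage_coefs[0] == pytest.approx(3.0, abs=1e-10)
        assert fit.second_stage_coefs[1] == pytest.approx(2.5, abs=1e-10)

    def test_frisch_waugh_lovell_orthogonal_covariates(self, rng):
        # covariates orthogonal to both strength and outcome leave the
        # strength coefficient unchanged under nuisance residualization
        n = 60
        S = rng.standard_normal((n, 1))
        y = 1.0 + 0.8 * S[:, 0] + 0.3 * rng.standard_normal(n)
        C = rng.standard_normal((n, 2))
        span = np.column_stack([np.ones(n), S[:, 0], y])
        C = C - span @ np.linalg.lstsq(span, C, rcond=None)[0]
        cfg_none = ModelConfig(covariate_mode="none")
        cfg_nuis = ModelConfig(covariate_mode="nuisance", covariates=("c1", "c2"))
        fit_none = fit_second_stage(S, y, None, cfg_none)
        fit_nuis = fit_second_stage(S, y, C, cfg_nuis, covariate_names=["c1", "c2"])
        assert fit_nuis.second_stage_coefs[1] == pytest.approx(
            fit_none.second_stage_coefs[1], abs=1e-8
        )

    def test_predictor_mode_zero_effect_covariate_near_zero(self):
        rng = np.random.default_rng(17)
        n = 300
        S = rng.standard_normal((n, 1))
        C = rng.standard_normal((n, 1))  # no influence on y
        y = 2.0 + 1.5 * S[:, 0] + 0.5 * rng.standard_normal(n)
        cfg = ModelConfig(covariate_mode="predictors", covariates=("c",))
        fit = fit_second_stage(S, y, C, cfg, covariate_names=["c"])
        assert abs(fit.second_stage_coefs[2]) < 0.1

    def test_rank_deficient_design_names_columns(self, rng):
        n = 30
        S = rng.standard_normal((n, 1))
        C = np.column_stack([S[:, 0], rng.standard_normal(n)])  # duplicates strength
        cfg = ModelConfig(covariate_mode="predictors", covariates=("dup", "ok"))
        with pytest.raises(ValueError, match="dup"):
            fit_second_stage(S, y := rng.standard_normal(n), C, cfg,
                             covariate_names=["dup", "ok"])

    def test_empty_selection_reduces_to_intercept(self, rng):
        S = np.zeros((20, 1))
        y = rng.standard_normal(20) + 5
        fit = fit_second_stage(S, y, None, ModelConfig())
        assert fit.empty_selection
        assert fit.second_stage_coefs[1] == 0.0
        assert fit.second_stage_coefs[0] == pytest.approx(y.mean())


class TestPredict:
    def _noise_free_setup(self, n=24, n_feat=12, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, n_feat))
        y = 4.0 + 1.2 * (X[:, 2] + X[:, 7])
        return X, y

    def test_heldout_subject_predicted_exactly_noise_free(self):
        X, y = self._noise_free_setup()
        cohort = make_cohort_frame(y)
        fit = fit_model(X[:-1], cohort.iloc[:-1], ModelConfig())
        pred = predict(fit, X[-1:], cohort.iloc[[-1]])
        assert pred[0] == pytest.approx(y[-1], abs=1e-8)

    def test_zero_nuisance_effects_train_test_sources_agree(self, rng):
        # covariate constructed with exactly zero estimated effect on the
        # outcome and the strength in BOTH subsets: the train-source and
        # test-source residualizations are then the identity, so the two
        # prediction routes must coincide
        n = 30
        X = rng.standard_normal((n, 10))
        y = 2.0 + X[:, 0]
        age = rng.uniform(8, 17, n)
        for rows in (slice(0, 20), slice(20, 30)):
            span = np.column_stack([np.ones(rows.stop - rows.start), X[rows, 0]])
            age[rows] -= span @ np.linalg.lstsq(span, age[rows], rcond=None)[0]
        C_frame = make_cohort_frame(y, age=age)
        cfg = ModelConfig(covariate_mode="nuisance", covariates=("age_years",),
                          alpha_select=1e-10)  # only the exact feature survives
        fit = fit_model(X[:20], C_frame.iloc[:20], cfg)
        np.testing.assert_array_equal(fit.positive_idx, [0])
        p_train = predict(fit, X[20:], C_frame.iloc[20:], nuisance_source="train")
        p_test = predict(fit, X[20:], C_frame.iloc[20:], nuisance_source="test",
                         test_outcome=y[20:])
        np.testing.assert_allclose(p_train, p_test, atol=1e-8)
        np.testing.assert_allclose(p_train, y[20:], atol=1e-8)

    def test_manual_nuisance_oracle_on_small_fixture(self):
        # hand-specified 12-subject fixture; every step of the nuisance-mode
        # prediction is replicated with independent statsmodels fits
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        n = 12
        X = rng.standard_normal((n + 1, 6))
        age = rng.uniform(8, 17, n + 1)
        y = 3 + 2 * X[:, 1] + 0.3 * age + rng.standard_normal(n + 1)
        cohort = make_cohort_frame(y, age=age)
        cfg = ModelConfig(covariate_mode="nuisance", covariates=("age_years",),
                          alpha_select=0.05)
        fit = fit_model(X[:n], cohort.iloc[:n], cfg)
        got = predict(fit, X[n:], cohort.iloc[[n]], nuisance_source="train")[0]

        # oracle: first-stage selection indices taken from the fit, the rest
        # recomputed from scratch with statsmodels
        S_tr = X[:n][:, fit.positive_idx].sum(axis=1)
        Z_tr = sm.add_constant(age[:n])
        nuis_y = sm.OLS(y[:n], Z_tr).fit().params
        nuis_s = sm.OLS(S_tr, Z_tr).fit().params
        yr = y[:n] - Z_tr @ nuis_y
        Sr = S_tr - Z_tr @ nuis_s
        beta = sm.OLS(yr, sm.add_constant(Sr)).fit().params
        S_te = X[n][fit.positive_idx].sum()
        Sr_te = S_te - np.array([1.0, age[n]]) @ nuis_s
        expected = beta[0] + beta[1] * Sr_te + np.array([1.0, age[n]]) @ nuis_y
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_test_subject_cannot_use_test_nuisance(self, rng):
        X, y = self._noise_free_setup()
        cohort = make_cohort_frame(y)
        cfg = ModelConfig(covariate_mode="nuisance", covariates=("age_years",))
        fit = fit_model(X[:-1], cohort.iloc[:-1], cfg)
        with pytest.raises(ValueError, match="single test subject"):
            predict(fit, X[-1:], cohort.iloc[[-1]], nuisance_source="test",
                    test_outcome=y[-1:])


class TestLooCV:
    def test_noise_free_cohort_perfect_metrics(self):
        rng = np.random.default_rng(13)
        n = 26
        X = rng.standard_normal((n, 20))
        y = 5.0 + 1.5 * X[:, 3]
        rep = loo_cv(X, make_cohort_frame(y), ModelConfig(), n_boot=100, seed=0)
        assert rep.mae < 1e-6
        assert rep.r > 0.999999
        assert rep.r2 > 0.999999

    def test_planted_edges_cross_fold_frequency(self, planted_cohort):
        c = planted_cohort
        in_a = c.dataset("A")
        rep = loo_cv(
            c.edges_session1.matrix[in_a], c.phenotypes[in_a],
            ModelConfig(), n_boot=100, seed=1,
        )
        freq = rep.selection_frequency
        assert np.all(freq[c.signal_edge_idx] >= 0.5)
        null_mask = np.ones(freq.size, dtype=bool)
        null_mask[c.signal_edge_idx] = False
        assert (freq[null_mask] >= 0.5).mean() < 0.01
        assert rep.r >= 0.7
        # the >= 50%-of-folds reporting rule fires on the planted truth
        assert set(c.signal_edge_idx) <= set(rep.frequent_features(0.5))

    def test_no_leakage_from_heldout_outcome(self):
        # permuting a held-out subject's outcome must not change its
        # prediction: it never participates in selection, fitting, or
        # nuisance estimation
        rng = np.random.default_rng(23)
        n = 16
        X = rng.standard_normal((n, 30))
        y = X[:, 0] + rng.standard_normal(n)
        cohort = make_cohort_frame(y)
        cfg = ModelConfig(covariate_mode="nuisance",
                          covariates=("age_years", "sex"), alpha_select=0.05)
        rep = loo_cv(X, cohort, cfg, n_boot=50, seed=0)
        for i in (0, n // 2, n - 1):
            cohort2 = cohort.copy()
            cohort2.loc[cohort2.index[i], "pars_post"] = -999.0
            rep2 = loo_cv(X, cohort2, cfg, n_boot=50, seed=0)
            assert rep2.predicted[i] == rep.predicted[i]

    def test_change_score_equals_post_with_baseline_covariate_noise_free(self):
        # when the true post score is exactly (signal + 1 * baseline), the
        # change-score model and the post-score model with baseline as a
        # predictor (fitted coefficient 1) make identical predictions
        rng = np.random.default_rng(29)
        n = 24
        X = rng.standard_normal((n, 10))
        baseline = rng.uniform(9, 25, n)
        y = 2.0 + 1.3 * X[:, 4] + baseline
        cohort = make_cohort_frame(y, baseline=baseline)
        cfg_change = ModelConfig(outcome="change_score")
        cfg_post = ModelConfig(outcome="post_score", covariate_mode="predictors",
                               covariates=("pars_baseline",))
        rep_change = loo_cv(X, cohort, cfg_change, n_boot=50, seed=0)
        rep_post = loo_cv(X, cohort, cfg_post, n_boot=50, seed=0)
        np.testing.assert_allclose(
            rep_post.predicted - baseline, rep_change.predicted, atol=1e-8
        )

    def test_pure_noise_r2_not_positive_on_average(self):
        rng = np.random.default_rng(37)
        r2s = []
        for _ in range(25):
            X = rng.standard_normal((20, 80))
            y = rng.standard_normal(20)
            rep = loo_cv(X, make_cohort_frame(y), ModelConfig(alpha_select=0.05),
                         n_boot=20, seed=0)
            r2s.append(rep.r2)
        assert np.mean(r2s) <= 0


class TestExternalValidation:
    def test_self_validation_equals_in_sample_fit(self, rng):
        n = 30
        X = rng.standard_normal((n, 15))
        y = 1.0 + X[:, 2] + 0.2 * rng.standard_normal(n)
        cohort = make_cohort_frame(y)
        rep = external_validation(X, cohort, X, cohort, ModelConfig(),
                                  n_boot=100, seed=0)
        fit = fit_model(X, cohort, ModelConfig())
        yhat = predict(fit, X, cohort)
        np.testing.assert_allclose(rep.predicted, yhat, atol=1e-12)

    def test_matched_generators_give_comparable_r(self, planted_cohort):
        c = planted_cohort
        in_a, in_b = c.dataset("A"), c.dataset("B")
        X = c.edges_session1.matrix
        rep_loo = loo_cv(X[in_a], c.phenotypes[in_a], ModelConfig(),
                         n_boot=50, seed=0)
        rep_ext = external_validation(
            X[in_a], c.phenotypes[in_a], X[in_b], c.phenotypes[in_b],
            ModelConfig(), n_boot=50, seed=0,
        )
        assert rep_ext.r > 0.5
        assert abs(rep_ext.r - rep_loo.r) < 0.3

    def test_reverse_direction_runs(self, planted_cohort):
        c = planted_cohort
        in_a, in_b = c.dataset("A"), c.dataset("B")
        X = c.edges_session1.matrix
        rep = external_validation(
            X[in_b], c.phenotypes[in_b], X[in_a], c.phenotypes[in_a],
            ModelConfig(), n_boot=50, seed=0,
        )
        assert np.all(np.isfinite(rep.predicted))

    def test_feature_space_mismatch_rejected(self, rng):
        y = rng.standard_normal(15)
        with pytest.raises(ValueError, match="mismatch"):
            external_validation(
                rng.standard_normal((15, 10)), make_cohort_frame(y),
                rng.standard_normal((5, 11)), make_cohort_frame(y[:5]),
                ModelConfig(),
            )


class TestCovariates:
    def test_scanner_expanded_to_indicators(self):
        y = np.arange(12.0)
        cohort = make_cohort_frame(y, scanner=np.array([0] * 6 + [1] * 3 + [2] * 3))
        cfg = ModelConfig(covariate_mode="predictors", covariates=("scanner",))
        C, names = build_covariates(cohort, cfg)
        assert names == ["scanner[1]", "scanner[2]"]
        assert C.shape == (12, 2)
        np.testing.assert_array_equal(C.sum(axis=0), [3, 3])

    def test_unknown_covariate_rejected(self):
        cohort = make_cohort_frame(np.arange(10.0))
        cfg = ModelConfig(covariate_mode="predictors", covariates=("iq",))
        with pytest.raises(ValueError, match="iq"):
            build_covariates(cohort, cfg)

    def test_zero_effect_covariates_leave_loo_metrics_close(self):
        rng = np.random.default_rng(41)
        n = 30
        X = rng.standard_normal((n, 40))
        y = 1.0 + X[:, 5] + 0.3 * rng.standard_normal(n)
        cohort = make_cohort_frame(y)  # age/sex have no effect on y
        rep0 = loo_cv(X, cohort, ModelConfig(), n_boot=20, seed=0)
        rep1 = loo_cv(X, cohort,
                      ModelConfig(covariate_mode="predictors",
                                  covariates=("age_years", "sex")),
                      n_boot=20, seed=0)
        assert abs(rep0.r - rep1.r) < 0.25


class TestDPSelection:
    def test_dp_selected_features_feed_cpm(self, small_cohort):
        from connpredict.fingerprint import differential_power, phat

        c = small_cohort
        in_a = c.dataset("A")
        dp_res = differential_power(
            phat(c.edges_session1.matrix[in_a], c.edges_session2.matrix[in_a])
        )
        cfg = ModelConfig(selection="dp", dp_alpha=0.2)
        rep = loo_cv(c.edges_session1.matrix[in_a], c.phenotypes[in_a], cfg,
                     dp_result=dp_res, n_boot=20, seed=0)
        assert np.all(np.isfinite(rep.predicted))
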