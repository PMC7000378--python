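"""Stratified splitting, the penalized logistic fit, and prediction."""

import numpy as np
import pandas as pd
import pytest

from roiclassify import (FittedModel, fit_logistic, predict_probability,
                         ratio_sweep, stratified_split)
from roiclassify.model import COVARIATE_NAMES, _nll

from conftest import make_feature_table


def _labels(n_cases, n_controls):
    idx = [f"s{i}" for i in range(n_cases + n_controls)]
    return pd.Series([1] * n_cases + [0] * n_controls, index=idx)


class TestStratifiedSplit:
    def test_exact_halves_at_even_ratio(self):
        split = stratified_split(_labels(10, 10), ratio=0.5, seed=0)
        assert len(split.train_ids) == 10 and len(split.test_ids) == 10

    def test_determinism_and_seed_sensitivity(self):
        y = _labels(12, 9)
        a = stratified_split(y, 0.7, seed=4)
        b = stratified_split(y, 0.7, seed=4)
        c = stratified_split(y, 0.7, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids != c.train_ids

    def test_study_sized_split_rounds_half_up_per_class(self):
        # 0.7 * 38 = 26.6 -> 27 case rows in train; 0.7 * 31 = 21.7 -> 22
        y = _labels(38, 31)
        split = stratified_split(y, 0.7, seed=0)
        train_y = y.loc[split.train_ids]
        assert int((train_y == 1).sum()) == 27
        assert int((train_y == 0).sum()) == 22
        assert len(split.test_ids) == 20

    def test_partition_is_disjoint_and_complete(self):
        y = _labels(7, 5)
        split = stratified_split(y, 0.6, seed=1)
        assert set(split.train_ids).isdisjoint(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(y.index)

    def test_ratio_bounds_enforced(self):
        with pytest.raises(ValueError, match="ratio"):
            stratified_split(_labels(5, 5), ratio=0.95, seed=0)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(pd.Series([1, 0, 0, 0]), ratio=0.5, seed=0)


class TestFitLogistic:
    def test_null_signal_predicts_prevalence(self):
        table = make_feature_table(n_subjects=300, n_regions=5, seed=20,
                                   prevalence=0.3)
        mdl = fit_logistic(table, table.labels)
        p = mdl.predict_proba(table)
        prevalence = table.labels.mean()
        assert abs(p.mean() - prevalence) < 0.05
        assert all(abs(b) < 0.5 for b in mdl.coefficients.values())

    def test_separable_data_classified_perfectly_on_train(self):
        table = make_feature_table(n_subjects=40, n_regions=2, seed=21)
        counts = table.counts.copy()
        counts[1] = 10 + 50 * table.labels  # perfectly separating feature
        table.counts = counts
        mdl = fit_logistic(table, table.labels, penalty=1e-4)
        assert (mdl.predict(table) == table.labels).all()

    def test_matches_independent_convex_optimizer(self):
        # oracle: generic BFGS on a re-derived penalized likelihood
        from scipy.optimize import minimize

        table = make_feature_table(n_subjects=60, n_regions=4, seed=22,
                                   effect_regions=(2,), effect=10.0)
        alpha = 0.05
        mdl = fit_logistic(table, table.labels, covariates=False,
                           penalty=alpha, gtol=1e-12, maxiter=300)
        X = table.counts.to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = table.labels.to_numpy(dtype=float)

        def neg_loglik(beta):
            z = beta[0] + X @ beta[1:]
            ll = y * np.log1p(np.exp(-z)) + (1 - y) * np.log1p(np.exp(z))
            return ll.mean() + 0.5 * alpha * (beta[1:] @ beta[1:])

        res = minimize(neg_loglik, np.zeros(5), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        mine = np.r_[mdl.intercept,
                     [mdl.coefficients[r] for r in table.counts.columns]]
        assert np.allclose(mine, res.x, rtol=1e-4, atol=1e-6)

    def test_matches_sklearn_with_matched_penalty(self):
        from sklearn.linear_model import LogisticRegression

        table = make_feature_table(n_subjects=80, n_regions=6, seed=23,
                                   effect_regions=(1,), effect=8.0)
        n = table.n_subjects
        mdl = fit_logistic(table, table.labels, covariates=False,
                           gtol=1e-12, maxiter=300)  # default alpha = 1/n
        X = table.counts.to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        skl = LogisticRegression(C=1.0, tol=1e-12, max_iter=5000)
        skl.fit(X, table.labels)
        mine = np.array([mdl.coefficients[r] for r in table.counts.columns])
        assert np.allclose(mine, skl.coef_[0], rtol=1e-4, atol=1e-6)
        assert mdl.intercept == pytest.approx(skl.intercept_[0], rel=1e-3,
                                              abs=1e-6)

    def test_deviance_never_worse_than_null_model(self):
        table = make_feature_table(n_subjects=50, n_regions=5, seed=24)
        mdl = fit_logistic(table, table.labels)
        X = mdl.design(table)
        beta = np.r_[mdl.intercept,
                     [mdl.coefficients[r] for r in mdl.selected_region_ids],
                     list(mdl.covariate_coefficients.values())]
        y = table.labels.to_numpy(dtype=float)
        fitted = _nll(beta, X, y, 0.0)
        null = _nll(np.zeros_like(beta), X, y, 0.0)
        assert fitted <= null

    def test_scaling_and_coefficients_ignore_test_rows(self):
        table = make_feature_table(n_subjects=40, n_regions=6, seed=25)
        split = stratified_split(table.labels, 0.7, seed=0)
        train = table.subset(split.train_ids)
        y_train = table.labels.loc[split.train_ids]
        before = fit_logistic(train, y_train)
        # corrupt every test-set row; the fit must not notice
        table.counts.loc[split.test_ids] = 999
        after = fit_logistic(table.subset(split.train_ids), y_train)
        assert before.feature_scaling == after.feature_scaling
        assert before.coefficients == after.coefficients

    def test_sgd_option_approximates_newton_solution(self):
        table = make_feature_table(n_subjects=120, n_regions=3, seed=26,
                                   effect_regions=(2,), effect=12.0)
        newton = fit_logistic(table, table.labels, penalty=0.1)
        sgd = fit_logistic(table, table.labels, penalty=0.1, method="sgd",
                           seed=7)
        for r in table.counts.columns:
            assert sgd.coefficients[r] == pytest.approx(newton.coefficients[r],
                                                        abs=0.15)

    def test_negative_penalty_rejected(self):
        table = make_feature_table(n_subjects=20, n_regions=3, seed=27)
        with pytest.raises(ValueError, match="penalty"):
            fit_logistic(table, table.labels, penalty=-1.0)


class TestPredictProbability:
    def _model(self, intercept, coefs, scaling=None):
        region_ids = sorted(coefs)
        scaling = scaling or {str(r): (0.0, 1.0) for r in region_ids}
        return FittedModel(intercept=intercept, coefficients=coefs,
                           covariate_coefficients={},
                           feature_scaling=scaling,
                           selected_region_ids=region_ids)

    def test_symmetric_null_gives_half(self):
        mdl = self._model(0.0, {1: 0.0})
        assert predict_probability(mdl, {1: 3.0}) == pytest.approx(0.5)

    def test_logistic_limits(self):
        mdl = self._model(0.0, {1: 1.0})
        assert predict_probability(mdl, {1: 0.0}) == pytest.approx(0.5)
        assert predict_probability(mdl, {1: 1e4}) == pytest.approx(1.0)
        assert predict_probability(mdl, {1: -1e4}) == pytest.approx(0.0)

    def test_closed_form_evaluation(self):
        mdl = self._model(1.0, {1: 2.0})
        expected = 1.0 / (1.0 + np.exp(-3.0))
        assert predict_probability(mdl, {1: 1.0}) == pytest.approx(expected)

    def test_missing_feature_named_in_error(self):
        mdl = self._model(0.0, {1: 1.0, 2: 1.0})
        with pytest.raises(KeyError, match="2"):
            predict_probability(mdl, {1: 1.0})

    def test_monotone_in_feature_with_coefficient_sign(self):
        mdl = self._model(0.2, {1: 1.5, 2: -0.7})
        up = [predict_probability(mdl, {1: x, 2: 0.0}) for x in (-1, 0, 1, 2)]
        down = [predict_probability(mdl, {1: 0.0, 2: x}) for x in (-1, 0, 1, 2)]
        assert up == sorted(up)
        assert down == sorted(down, reverse=True)

    def test_round_trip_through_json_dict(self):
        table = make_feature_table(n_subjects=30, n_regions=4, seed=28)
        mdl = fit_logistic(table, table.labels)
        back = FittedModel.from_dict(mdl.to_dict())
        row = {**{r: table.counts[r].iloc[0] for r in table.counts.columns},
               "age": table.covariates["age"].iloc[0],
               "sex": table.covariates["sex"].iloc[0]}
        assert predict_probability(back, row) == pytest.approx(
            predict_probability(mdl, row))


class TestRatioSweep:
    def test_one_entry_per_ratio_seed_pair(self):
        table = make_feature_table(n_subjects=40, n_regions=6, seed=29)
        per_run, summary = ratio_sweep(table, table.labels,
                                       ratios=(0.5, 0.7), seeds=(0, 1),
                                       rfe_target=3)
        assert len(per_run) == 4
        assert set(summary["ratio"]) == {0.5, 0.7}

    def test_pure_noise_accuracy_near_prevalence(self):
        table = make_feature_table(n_subjects=60, n_regions=8, seed=30)
        per_run, _ = ratio_sweep(table, table.labels, ratios=(0.5, 0.7),
                                 seeds=(0, 1, 2), rfe_target=4)
        prevalence = max(table.labels.mean(), 1 - table.labels.mean())
        assert abs(per_run["test_accuracy"].mean() - prevalence) < 0.25

    def test_requires_two_ratios_and_two_seeds(self):
        table = make_feature_table(n_subjects=30, n_regions=4, seed=31)
        with pytest.raises(ValueError, match="2 ratios"):
            ratio_sweep(table, table.labels, ratios=(0.7,), seeds=(0, 1))
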