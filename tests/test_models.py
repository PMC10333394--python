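"""Model training, metrics, calibration and attribution."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from pacuseq import (
    BalanceSpec,
    CohortConfig,
    ModelSpec,
    auc_score,
    calibration_curve,
    cross_validate,
    encode_features,
    evaluate_on_test,
    feature_importance,
    generate_cohort,
    predict_risk,
    train_model,
)
from conftest import imbalanced_matrix, make_matrix


def pair_counting_auc(labels, scores):
    """Brute-force AUC oracle: fraction of positive-negative pairs won,
    ties counting one half."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    wins = ties = total = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            total += 1
            if s[i] > s[j]:
                wins += 1
            elif s[i] == s[j]:
                ties += 1
    return (wins + 0.5 * ties) / total


class TestAuc:
    def test_hand_worked_example(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        assert auc_score(labels, scores) == pytest.approx(8 / 9)
        assert pair_counting_auc(labels, scores) == pytest.approx(8 / 9)

    def test_perfect_and_anti_predictor(self):
        y = [0, 0, 1, 1]
        assert auc_score(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_score(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_constant_score_is_half_by_tie_convention(self):
        assert auc_score([0, 1, 0, 1], [0.3] * 4) == 0.5

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert auc_score(y, s) == pytest.approx(pair_counting_auc(y, s))


class TestTraining:
    def test_logistic_separable_toy_perfect_accuracy(self):
        X = np.array([[0.0, 0], [0.1, 0], [1.0, 1], [1.1, 1],
                      [0.2, 0], [0.9, 1]])
        fm = make_matrix(X[:, :1], X[:, 1].astype(int))
        handle = train_model(ModelSpec(family="logistic"), fm)
        pred = (predict_risk(handle, fm) >= 0.5).astype(int)
        assert (pred.to_numpy() == fm.y.to_numpy()).all()

    def test_logistic_matches_direct_likelihood_optimization(self):
        # oracle: minimize 0.5 w'w + C * sum log(1 + exp(-y f)) directly
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = (X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.5, 20) > 0).astype(int)
        fm = make_matrix(X, y)
        handle = train_model(
            ModelSpec(family="logistic", hyperparameters={"tol": 1e-12}), fm)
        sk = handle.estimator

        C = 6.0
        ys = 2.0 * y - 1.0

        def objective(params):
            w, b = params[:3], params[3]
            margins = ys * (X @ w + b)
            return 0.5 * w @ w + C * np.sum(np.logaddexp(0.0, -margins))

        res = minimize(objective, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.allclose(sk.coef_.ravel(), res.x[:3], atol=1e-4)
        assert np.isclose(sk.intercept_[0], res.x[3], atol=1e-4)

    @pytest.mark.parametrize("family,overrides", [
        ("logistic", {}),
        ("neural_net", {"max_iter": 30}),
        ("xgboost", {"n_estimators": 20}),
        ("random_forest", {"n_estimators": 20}),
        ("balanced_random_forest", {"n_estimators": 20}),
        ("balanced_bagging", {"n_estimators": 20}),
    ])
    def test_all_families_emit_probabilities(self, family, overrides):
        fm = imbalanced_matrix(25, 75, seed=2)
        handle = train_model(
            ModelSpec(family=family, hyperparameters=overrides, seed=1), fm)
        risk = predict_risk(handle, fm).to_numpy()
        assert ((risk >= 0.0) & (risk <= 1.0)).all()

    def test_duplicated_positive_row_scores_high(self):
        X = np.vstack([np.tile([5.0, 5.0], (30, 1)),
                       np.random.default_rng(0).normal(0, 1, (70, 2))])
        y = np.array([1] * 30 + [0] * 70)
        fm = make_matrix(X, y)
        handle = train_model(
            ModelSpec(family="random_forest",
                      hyperparameters={"n_estimators": 30}), fm)
        assert predict_risk(handle, fm).iloc[0] > 0.5

    def test_degenerate_labels_rejected(self):
        fm = imbalanced_matrix(10, 40)
        fm.y[:] = 1
        with pytest.raises(ValueError):
            train_model(ModelSpec(family="logistic"), fm)

    def test_column_mismatch_names_columns(self):
        fm = imbalanced_matrix(20, 60)
        handle = train_model(ModelSpec(family="logistic"), fm)
        bad = dataclasses.replace(fm, X=fm.X.rename(columns={"f0": "zzz"}))
        with pytest.raises(ValueError, match="f0"):
            predict_risk(handle, bad)

    def test_hinge_margin_link_preserves_ranking(self):
        fm = imbalanced_matrix(40, 200, seed=7)
        handle = train_model(
            ModelSpec(family="xgboost", hyperparameters={"n_estimators": 30}),
            fm)
        import xgboost as xgb

        margin = handle.estimator.get_booster().predict(
            xgb.DMatrix(fm.X.to_numpy()), output_margin=True)
        risk = predict_risk(handle, fm).to_numpy()
        assert np.allclose(risk, expit(margin))
        assert auc_score(fm.y, margin) == pytest.approx(auc_score(fm.y, risk))


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        fm = imbalanced_matrix(30, 120, seed=1)
        spec = ModelSpec(family="logistic",
                         balance=BalanceSpec(smote_ratio=0.5, under_ratio=0.9))
        a = cross_validate(spec, fm, k=2, seed=3, n_boot=100)
        b = cross_validate(spec, fm, k=2, seed=3, n_boot=100)
        assert a == b

    def test_pooled_predictions_cover_every_training_row(self):
        fm = imbalanced_matrix(25, 100, seed=4)
        spec = ModelSpec(family="logistic",
                         balance=BalanceSpec(smote_ratio=0.6, under_ratio=0.8))
        report = cross_validate(spec, fm, k=5, seed=0, n_boot=100)
        # pooled out-of-fold vector has exactly one entry per training row:
        # no synthetic (SMOTE) row ever reaches evaluation
        assert report.n_eval == fm.n_rows

    def test_fold_losing_a_class_rejected(self):
        fm = imbalanced_matrix(3, 100)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(ModelSpec(family="logistic"), fm, k=5)


class TestEvaluation:
    def test_perfect_separation(self):
        fm = imbalanced_matrix(20, 40, seed=0)
        X = fm.X.copy()
        X["f0"] = fm.y * 10.0  # make class perfectly recoverable
        fm = dataclasses.replace(fm, X=X)
        handle = train_model(ModelSpec(family="logistic"), fm)
        report = evaluate_on_test(handle, fm, n_boot=100)
        assert report.auc == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_single_class_test_set_rejected(self):
        fm = imbalanced_matrix(20, 60)
        handle = train_model(ModelSpec(family="logistic"), fm)
        pos_only = fm.subset(fm.case_ids[fm.y == 1])
        with pytest.raises(ValueError):
            evaluate_on_test(handle, pos_only, n_boot=50)

    def test_bootstrap_ci_covers_known_auc(self):
        # binormal model: scores N(mu,1) vs N(0,1) => true AUC = Phi(mu/sqrt 2)
        from scipy.stats import norm

        from pacuseq.models import _stratified_bootstrap_ci

        mu = 1.2
        true_auc = norm.cdf(mu / np.sqrt(2.0))
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            y = np.array([1] * 40 + [0] * 80)
            s = np.concatenate([rng.normal(mu, 1, 40), rng.normal(0, 1, 80)])
            lo, hi = _stratified_bootstrap_ci(y, s, auc_score, n_boot=300,
                                              seed=int(rng.integers(1 << 30)))
            covered += lo <= true_auc <= hi
        assert covered / n_rep >= 0.90


class TestCalibration:
    def test_risk_equal_to_labels(self):
        y = np.array([0] * 50 + [1] * 50)
        bins = calibration_curve(y.astype(float), y, n_bins=10)
        assert all(rate == 0.0 for _, rate, _ in bins[:5])
        assert all(rate == 1.0 for _, rate, _ in bins[5:])

    def test_constant_risk_matches_prevalence(self):
        rng = np.random.default_rng(1)
        y = (rng.random(1000) < 0.3).astype(int)
        bins = calibration_curve(np.full(1000, 0.3), y, n_bins=10)
        for mean_risk, rate, _ in bins:
            assert mean_risk == pytest.approx(0.3)
            assert abs(rate - y.mean()) < 0.12

    def test_two_bin_hand_arithmetic(self):
        risk = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1])
        bins = calibration_curve(risk, labels, n_bins=2)
        assert bins[0] == (pytest.approx(0.3), pytest.approx(1 / 5), 5)
        assert bins[1] == (pytest.approx(0.8), pytest.approx(4 / 5), 5)

    def test_weighted_mean_equals_prevalence(self):
        rng = np.random.default_rng(3)
        risk = rng.random(987)
        y = (rng.random(987) < risk).astype(int)
        bins = calibration_curve(risk, y, n_bins=10)
        weighted = sum(rate * n for _, rate, n in bins) / sum(n for *_, n in bins)
        assert weighted == pytest.approx(y.mean(), abs=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.1, 0.9], [0, 1], n_bins=10)


@pytest.fixture(scope="module")
def duration_only_cohort():
    cfg = CohortConfig(
        n_cases=3000, seed=21,
        effect_sizes={"female_sex": 0.0, "log_duration": 0.5,
                      "bmi_z": 0.0, "age_z": 0.0})
    cohort = generate_cohort(cfg)
    return encode_features(cohort.cases)


class TestImportance:
    def test_planted_duration_effect_ranks_first(self, duration_only_cohort):
        fm = duration_only_cohort
        handle = train_model(
            ModelSpec(family="xgboost",
                      hyperparameters={"n_estimators": 100}), fm)
        report = feature_importance(handle, fm)
        assert report.method == "treeshap"
        assert report.ranking[0][0] == "scheduled_duration"

    def test_permutation_fallback_for_forest(self, duration_only_cohort):
        fm = duration_only_cohort.subset(duration_only_cohort.case_ids[:800])
        handle = train_model(
            ModelSpec(family="random_forest",
                      hyperparameters={"n_estimators": 30}), fm)
        report = feature_importance(handle, fm, n_repeats=3)
        assert report.method == "permutation"
        features = [f for f, _ in report.ranking]
        assert features.index("scheduled_duration") < len(features) / 2

    def test_default_effects_put_known_drivers_in_top_ranks(self, default_cohort_10k):
        fm = encode_features(default_cohort_10k.cases[:6000])
        handle = train_model(
            ModelSpec(family="xgboost",
                      hyperparameters={"n_estimators": 150}), fm)
        top5 = [f for f, _ in feature_importance(handle, fm).ranking[:5]]
        assert {"scheduled_duration", "bmi", "age"} <= set(top5)
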