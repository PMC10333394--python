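"""Six classifier families, cross-validation, held-out evaluation and
feature attribution for prolonged-PACU-stay risk.

Families: logistic regression, a single-hidden-layer feed-forward network,
XGBoost (hinge objective), random forest, balanced random forest (each
bootstrap under-sampled to near-parity) and balanced bagging.  Registry
defaults carry the tuned hyperparameter values for each family; each family
also carries its tuned SMOTE / under-sampling ratio pair (see
:mod:`pacuseq.balancing`).

Evaluation reports AUC, sensitivity and specificity with stratified-
bootstrap 95% confidence intervals, plus a decile calibration table
(observed event rate against mean predicted risk in ten equal-count bins).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalanceSpec, balance_pipeline
from .cohort import FeatureMatrix

logger = logging.getLogger(__name__)

MODEL_FAMILIES = (
    "logistic",
    "neural_net",
    "xgboost",
    "random_forest",
    "balanced_random_forest",
    "balanced_bagging",
)

#: Tuned hyperparameters shipped as registry defaults, per family.
DEFAULT_HYPERPARAMETERS = {
    "logistic": {"C": 6.0, "solver": "lbfgs", "max_iter": 2000, "tol": 1e-6},
    "neural_net": {
        "hidden_layers": 1,
        "neurons": 128,
        "max_iter": 100,
        "batch_size": 64,
        "learning_rate": 0.0001,
        "activation": "relu",
    },
    # The tuned tree depth of 300 is far beyond what 500 boosting rounds can
    # use on cohorts of this size; it is shipped as tuned but effectively
    # means "unbounded" and is overridable.
    "xgboost": {
        "objective": "binary:hinge",
        "colsample_bytree": 0.55,
        "learning_rate": 0.01,
        "max_depth": 300,
        "n_estimators": 500,
        "reg_lambda": 1.5,
    },
    "random_forest": {"n_estimators": 500},
    "balanced_random_forest": {"n_estimators": 2000, "sampling_strategy": 0.95},
    "balanced_bagging": {"n_estimators": 1200, "sampling_strategy": 1.0},
}


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    balance: BalanceSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.family == "xgboost" and self.hyperparameters["max_depth"] >= 100:
            logger.warning(
                "xgboost max_depth=%s is effectively unbounded; trees are "
                "limited by the data, not the depth cap",
                self.hyperparameters["max_depth"])

    @classmethod
    def with_tuned_balance(cls, family: str, seed: int = 0,
                           **hyper_overrides) -> "ModelSpec":
        """Spec with the family's tuned balance ratios attached."""
        return cls(family=family, hyperparameters=hyper_overrides,
                   balance=BalanceSpec.for_model(family, seed=seed), seed=seed)


class BalancedTreeEnsemble(BaseEstimator, ClassifierMixin):
    """Bagged decision trees where every bootstrap is rebalanced.

    Each member tree sees a bootstrap of the minority class plus a majority
    subsample of ``round(n_minority / sampling_strategy)`` rows, so class
    imbalance never reaches the base learner.  With ``max_features="sqrt"``
    this is a balanced random forest; with all features it is a balanced
    bagging classifier.
    """

    def __init__(self, n_estimators=100, sampling_strategy=1.0,
                 max_features=None, random_state=0):
        self.n_estimators = n_estimators
        self.sampling_strategy = sampling_strategy
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        rng = np.random.default_rng(self.random_state)
        min_idx = np.flatnonzero(y == 1)
        maj_idx = np.flatnonzero(y == 0)
        n_take_maj = min(len(maj_idx),
                         int(round(len(min_idx) / self.sampling_strategy)))
        self.estimators_ = []
        for _ in range(self.n_estimators):
            boot_min = rng.choice(min_idx, size=len(min_idx), replace=True)
            boot_maj = rng.choice(maj_idx, size=n_take_maj, replace=False)
            idx = np.concatenate([boot_min, boot_maj])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        acc = np.zeros((len(X), 2))
        for tree in self.estimators_:
            proba = tree.predict_proba(X)
            for j, cls in enumerate(tree.classes_):
                acc[:, int(cls)] += proba[:, j]
        return acc / len(self.estimators_)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.family == "logistic":
        return LogisticRegression(C=hp["C"], solver=hp["solver"],
                                  max_iter=hp["max_iter"], tol=hp["tol"],
                                  random_state=spec.seed)
    if spec.family == "neural_net":
        if hp["hidden_layers"] != 1:
            raise ValueError("the shallow network has exactly one hidden layer")
        mlp = MLPClassifier(
            hidden_layer_sizes=(hp["neurons"],),
            activation=hp["activation"],
            max_iter=hp["max_iter"],
            batch_size=hp["batch_size"],
            learning_rate_init=hp["learning_rate"],
            random_state=spec.seed,
        )
        # the network needs standardized inputs; scaling is its own concern
        return Pipeline([("scale", StandardScaler()), ("mlp", mlp)])
    if spec.family == "xgboost":
        return xgb.XGBClassifier(
            objective=hp["objective"],
            colsample_bytree=hp["colsample_bytree"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"],
            n_estimators=hp["n_estimators"],
            reg_lambda=hp["reg_lambda"],
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(n_estimators=hp["n_estimators"],
                                      random_state=spec.seed, n_jobs=1)
    if spec.family == "balanced_random_forest":
        return BalancedTreeEnsemble(
            n_estimators=hp["n_estimators"],
            sampling_strategy=hp["sampling_strategy"],
            max_features="sqrt",
            random_state=spec.seed,
        )
    if spec.family == "balanced_bagging":
        return BalancedTreeEnsemble(
            n_estimators=hp["n_estimators"],
            sampling_strategy=hp["sampling_strategy"],
            max_features=None,
            random_state=spec.seed,
        )
    raise AssertionError(spec.family)


@dataclass
class FittedModel:
    """Handle pairing a fitted estimator with its training column contract."""

    spec: ModelSpec
    estimator: object
    columns: list


def train_model(spec: ModelSpec, train: FeatureMatrix) -> FittedModel:
    """Balance the training rows (when a BalanceSpec is attached), then fit."""
    if train.y.nunique() < 2:
        raise ValueError("training labels are degenerate (single class)")
    balanced = balance_pipeline(train, spec.balance) if spec.balance else train
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter at max_iter=100
        estimator.fit(balanced.X.to_numpy(dtype=float),
                      balanced.y.to_numpy(dtype=int))
    return FittedModel(spec=spec, estimator=estimator,
                       columns=list(train.X.columns))


def predict_risk(handle: FittedModel, matrix: FeatureMatrix) -> pd.Series:
    """P(prolonged) per row, aligned to the matrix index.

    The hinge-objective booster emits margins, not probabilities; they are
    mapped through the logistic function, a strictly monotone link, so
    ranking-based uses (AUC, resequencing order) are unaffected.
    """
    if list(matrix.X.columns) != handle.columns:
        missing = sorted(set(handle.columns) - set(matrix.X.columns))
        extra = sorted(set(matrix.X.columns) - set(handle.columns))
        raise ValueError(
            f"feature columns differ from training: missing={missing}, "
            f"unexpected={extra}")
    Xa = matrix.X.to_numpy(dtype=float)
    est = handle.estimator
    if handle.spec.family == "xgboost":
        margin = est.get_booster().predict(xgb.DMatrix(Xa), output_margin=True)
        risk = expit(margin)
    else:
        risk = est.predict_proba(Xa)[:, 1]
    return pd.Series(np.asarray(risk, dtype=float), index=matrix.case_ids,
                     name="risk")


# --- metrics ------------------------------------------------------------

def auc_score(labels, risk) -> float:
    """Rank-statistic AUC with the standard tie correction."""
    return float(roc_auc_score(np.asarray(labels, int), np.asarray(risk, float)))


def sensitivity_specificity(labels, risk, threshold: float = 0.5):
    y = np.asarray(labels, int)
    pred = np.asarray(risk, float) >= threshold
    sens = float(pred[y == 1].mean()) if (y == 1).any() else float("nan")
    spec = float((~pred[y == 0]).mean()) if (y == 0).any() else float("nan")
    return sens, spec


def _stratified_bootstrap_ci(labels, risk, stat_fn, n_boot: int, seed: int,
                             alpha: float = 0.05):
    """Percentile CI resampling positives and negatives separately."""
    y = np.asarray(labels, int)
    r = np.asarray(risk, float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        stats_[b] = stat_fn(y[idx], r[idx])
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    point = stat_fn(y, r)  # percentile interval widened to bracket the point
    return float(min(lo, point)), float(max(hi, point))


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    threshold: float
    calibration_bins: list  # (mean predicted risk, observed rate, count)
    n_eval: int

    def __post_init__(self):
        for point, (lo, hi) in (
            (self.auc, self.auc_ci),
            (self.sensitivity, self.sensitivity_ci),
            (self.specificity, self.specificity_ci),
        ):
            if not (lo <= point + 1e-12 and point <= hi + 1e-12):
                raise ValueError("CI must bracket the point estimate")
        total = sum(c for _, _, c in self.calibration_bins)
        if total != self.n_eval:
            raise ValueError("calibration bin counts must sum to n_eval")

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def calibration_curve(risk, labels, n_bins: int = 10):
    """Equal-count risk-decile calibration table.

    Rows are sorted by predicted risk (stable, so ties keep input order) and
    split into ``n_bins`` near-equal bins; each bin reports (mean predicted
    risk, observed event rate, count).  The count-weighted mean of observed
    rates therefore equals the overall prevalence exactly.
    """
    r = np.asarray(risk, float)
    y = np.asarray(labels, int)
    if len(r) != len(y):
        raise ValueError("risk and labels must be aligned")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(r) < n_bins:
        raise ValueError(f"need at least {n_bins} rows for {n_bins} bins")
    order = np.argsort(r, kind="stable")
    bins = []
    for chunk in np.array_split(order, n_bins):
        bins.append((float(r[chunk].mean()), float(y[chunk].mean()), len(chunk)))
    return bins


def _evaluate_vector(labels, risk, threshold, n_boot, seed, n_bins=10):
    sens, spec = sensitivity_specificity(labels, risk, threshold)
    return EvalReport(
        auc=auc_score(labels, risk),
        auc_ci=_stratified_bootstrap_ci(labels, risk, auc_score, n_boot, seed),
        sensitivity=sens,
        sensitivity_ci=_stratified_bootstrap_ci(
            labels, risk,
            lambda y, r: sensitivity_specificity(y, r, threshold)[0],
            n_boot, seed + 1),
        specificity=spec,
        specificity_ci=_stratified_bootstrap_ci(
            labels, risk,
            lambda y, r: sensitivity_specificity(y, r, threshold)[1],
            n_boot, seed + 2),
        threshold=threshold,
        calibration_bins=calibration_curve(risk, labels, n_bins),
        n_eval=len(labels),
    )


def cross_validate(spec: ModelSpec, train: FeatureMatrix, k: int = 10,
                   seed: int = 0, threshold: float = 0.5,
                   n_boot: int = 2000) -> EvalReport:
    """Stratified k-fold CV with balancing applied inside each fold only.

    Out-of-fold predictions are pooled across folds and metrics are computed
    once on the pooled vector, so every training row is scored exactly once
    and no synthetic row ever reaches evaluation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = train.y.to_numpy(int)
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError(
            f"a class has fewer than k={k} members; folds would lose a class "
            "— use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(train.n_rows, np.nan)
    ids = train.case_ids
    for fold, (tr_idx, va_idx) in enumerate(skf.split(train.X, y)):
        fold_spec = dataclasses.replace(spec, seed=spec.seed + fold,
                                        hyperparameters=dict(spec.hyperparameters))
        handle = train_model(fold_spec, train.subset(ids[tr_idx]))
        oof[va_idx] = predict_risk(handle, train.subset(ids[va_idx])).to_numpy()
    assert not np.isnan(oof).any()
    return _evaluate_vector(y, oof, threshold, n_boot, seed)


def evaluate_on_test(handle: FittedModel, test: FeatureMatrix,
                     threshold: float = 0.5, n_boot: int = 2000,
                     seed: int = 0) -> EvalReport:
    """Held-out evaluation; the test matrix must never have been balanced."""
    y = test.y.to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class")
    risk = predict_risk(handle, test).to_numpy()
    return _evaluate_vector(y, risk, threshold, n_boot, seed)


def plot_evaluation(labels, risk, roc_path, calibration_path, n_bins: int = 10):
    """Write ROC and decile-calibration plots as image files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels, int), np.asarray(risk, float))
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, lw=1.5,
            label=f"AUC = {auc_score(labels, risk):.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(roc_path, dpi=150)
    plt.close(fig)

    bins = calibration_curve(risk, labels, n_bins=n_bins)
    pred = [b[0] for b in bins]
    obs = [b[1] for b in bins]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pred, obs, "o-", lw=1.5)
    lim = max(max(pred), max(obs)) * 1.1 or 1.0
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("Mean predicted risk (decile)")
    ax.set_ylabel("Observed event rate")
    fig.tight_layout()
    fig.savefig(calibration_path, dpi=150)
    plt.close(fig)


@dataclass
class ImportanceReport:
    method: str  # "treeshap" or "permutation"
    ranking: list  # (feature, importance), descending


def feature_importance(handle: FittedModel, matrix: FeatureMatrix,
                       seed: int = 0, n_repeats: int = 5) -> ImportanceReport:
    """Mean absolute per-feature attribution, descending.

    XGBoost models use the booster's exact tree-SHAP contributions
    (``pred_contribs``); other families fall back to AUC-scored permutation
    importance, and the report says which method produced it.
    """
    Xa = matrix.X.to_numpy(dtype=float)
    if handle.spec.family == "xgboost":
        contribs = handle.estimator.get_booster().predict(
            xgb.DMatrix(Xa, feature_names=list(matrix.X.columns)),
            pred_contribs=True)
        scores = np.abs(contribs[:, :-1]).mean(axis=0)  # last column is bias
        method = "treeshap"
    else:
        logger.info("family %r has no exact SHAP path; using permutation "
                    "importance", handle.spec.family)
        result = permutation_importance(
            _RiskScorer(handle), matrix.X, matrix.y,
            scoring="roc_auc", n_repeats=n_repeats, random_state=seed)
        scores = result.importances_mean
        method = "permutation"
    order = np.argsort(-scores, kind="stable")
    ranking = [(matrix.X.columns[i], float(scores[i])) for i in order]
    return ImportanceReport(method=method, ranking=ranking)


class _RiskScorer(BaseEstimator, ClassifierMixin):
    """Adapter exposing predict_risk as decision_function for sklearn tools."""

    def __init__(self, handle):
        self.handle = handle
        self.classes_ = np.array([0, 1])
        self._is_fitted = True

    def fit(self, X, y):  # pragma: no cover - never refit
        return self

    def decision_function(self, X):
        fm = FeatureMatrix(
            pd.DataFrame(np.asarray(X, float),
                         columns=self.handle.columns,
                         index=pd.RangeIndex(len(X))),
            pd.Series(0, index=pd.RangeIndex(len(X)), dtype=int))
        return predict_risk(self.handle, fm).to_numpy()

    def __sklearn_is_fitted__(self):
        return True
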