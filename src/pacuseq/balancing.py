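"""Class rebalancing for the training split: SMOTE plus random under-sampling.

Prolonged PACU stays are rare (~5%), so classifiers trained on raw data
collapse toward the majority class.  The remedy used here is the combined
pipeline: SMOTE first inflates the minority class by interpolating between
each minority point and one of its k nearest minority neighbours, then
random under-sampling thins the majority class.  A "ratio" is always the
minority/majority count ratio *after* the step.  Both steps apply to
training rows only — never to validation or test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .cohort import FeatureMatrix

logger = logging.getLogger(__name__)

#: Per-model (smote_ratio, under_ratio) defaults.
DEFAULT_BALANCE_RATIOS = {
    "logistic": (0.75, 0.9),
    "neural_net": (0.4, 0.5),
    "xgboost": (0.5, 0.85),
    "random_forest": (0.8, 0.9),
    "balanced_random_forest": (0.35, 0.75),
    "balanced_bagging": (0.4, 0.6),
}


@dataclass
class BalanceSpec:
    """Sampling ratios for the combined SMOTE + under-sampling pipeline."""

    smote_ratio: float | None = None
    under_ratio: float | None = None
    k_neighbors: int = 5
    seed: int = 0
    scale_for_neighbors: bool = False  # z-scale features before the kNN search
    round_onehot: bool = False  # round interpolated one-hot columns to {0,1}

    def __post_init__(self):
        for name, r in (("smote_ratio", self.smote_ratio),
                        ("under_ratio", self.under_ratio)):
            if r is not None and not 0.0 < r <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    @classmethod
    def for_model(cls, family: str, seed: int = 0) -> "BalanceSpec":
        smote, under = DEFAULT_BALANCE_RATIOS[family]
        return cls(smote_ratio=smote, under_ratio=under, seed=seed)


def _class_counts(y: pd.Series):
    n_min = int((y == 1).sum())
    n_maj = int((y == 0).sum())
    return n_min, n_maj


def smote_oversample(matrix: FeatureMatrix, ratio: float, k_neighbors: int = 5,
                     seed: int = 0, scale_for_neighbors: bool = False,
                     round_onehot: bool = False) -> FeatureMatrix:
    """Append interpolated minority rows until minority = round(ratio * majority).

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]`` and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbours of the
    minority row ``x`` (Euclidean distance on the encoded matrix).  Majority
    rows are untouched.  A ratio at or below the current class ratio is a
    no-op with a logged warning.
    """
    n_min, n_maj = _class_counts(matrix.y)
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present")
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} members but k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    target = int(round(ratio * n_maj))
    need = target - n_min
    if need <= 0:
        logger.warning(
            "SMOTE ratio %.3f is at or below the current class ratio %.3f; "
            "returning input unchanged", ratio, n_min / n_maj)
        return matrix

    rng = np.random.default_rng(seed)
    Xmin = matrix.X[matrix.y == 1].to_numpy(dtype=float)
    search_space = (
        StandardScaler().fit_transform(Xmin) if scale_for_neighbors else Xmin
    )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(search_space)
    _, nbr_idx = nn.kneighbors(search_space)  # column 0 is the point itself

    base = rng.integers(0, len(Xmin), size=need)
    pick = rng.integers(1, k_neighbors + 1, size=need)
    neighbor = nbr_idx[base, pick]
    u = rng.random(size=(need, 1))
    synth = Xmin[base] + u * (Xmin[neighbor] - Xmin[base])
    if round_onehot:
        onehot_cols = [
            j for j, c in enumerate(matrix.X.columns)
            if set(np.unique(matrix.X[c])) <= {0.0, 1.0}
        ]
        synth[:, onehot_cols] = np.round(synth[:, onehot_cols])

    synth_ids = pd.Index([f"SMOTE{j:06d}" for j in range(need)], name="case_id")
    X_new = pd.concat(
        [matrix.X, pd.DataFrame(synth, index=synth_ids, columns=matrix.X.columns)]
    )
    y_new = pd.concat(
        [matrix.y, pd.Series(1, index=synth_ids, name=matrix.y.name, dtype=int)]
    )
    return FeatureMatrix(X_new, y_new)


def random_undersample(matrix: FeatureMatrix, ratio: float,
                       seed: int = 0) -> FeatureMatrix:
    """Subsample the majority class to round(minority / ratio) rows.

    Uniform, without replacement, minority untouched, original row order
    preserved.  A ratio that would require *up*sampling the majority is an
    error.
    """
    n_min, n_maj = _class_counts(matrix.y)
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present")
    keep = int(round(n_min / ratio))
    if keep > n_maj:
        raise ValueError(
            f"under-sampling ratio {ratio} needs {keep} majority rows but only "
            f"{n_maj} exist (would require upsampling the majority)"
        )
    rng = np.random.default_rng(seed)
    maj_pos = np.flatnonzero((matrix.y == 0).to_numpy())
    selected = np.sort(rng.choice(maj_pos, size=keep, replace=False))
    keep_mask = (matrix.y == 1).to_numpy()
    keep_mask[selected] = True
    ids = matrix.case_ids[keep_mask]
    return matrix.subset(ids)


def balance_pipeline(matrix: FeatureMatrix, spec: BalanceSpec) -> FeatureMatrix:
    """SMOTE first, then random under-sampling on the oversampled result.

    With both ratios ``None`` this is the identity.  Must only ever be
    applied to a training matrix.
    """
    out = matrix
    if spec.smote_ratio is not None:
        out = smote_oversample(
            out, spec.smote_ratio, spec.k_neighbors, spec.seed,
            scale_for_neighbors=spec.scale_for_neighbors,
            round_onehot=spec.round_onehot,
        )
    if spec.under_ratio is not None:
        out = random_undersample(out, spec.under_ratio, spec.seed + 1)
    return out
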