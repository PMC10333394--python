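"""Case-level data model, outcome labeling, feature encoding and train/test split.

The unit of analysis is a surgical *case* (one encounter); patients with
repeat encounters contribute one case per encounter.  The binary outcome is
prolonged post-anesthesia care unit (PACU) length of stay, defined as
``pacu_los >= 180`` minutes — the cohort's 75th-percentile stay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

#: Canonical binary outcome threshold, minutes (three hours).
PROLONGED_THRESHOLD_MIN = 180.0

#: The 16 comorbidity flags carried by every case, in canonical order.
COMORBIDITY_FLAGS = (
    "active_smoker",
    "alcohol_abuse_history",
    "anxiety",
    "asthma",
    "ckd",
    "copd",
    "chronic_pain",
    "cad",
    "depression",
    "dm",
    "dysrhythmias",
    "gerd",
    "seizure_history",
    "hypertension",
    "hypothyroidism",
    "osa",
)

SEX_LEVELS = ("female", "male")
ASA_LEVELS = (1, 2, 3, 4)
NUMERIC_FEATURES = ("age", "bmi", "scheduled_duration")


@dataclass
class PatientCase:
    """One surgical encounter with preoperative features and observed PACU stay.

    ``scheduled_start`` is minutes after midnight; ``pacu_los`` is minutes.
    ``prolonged`` stays ``None`` until :func:`label_cases` runs.
    """

    case_id: str
    date: Date
    surgeon_id: str
    scheduled_start: float
    scheduled_duration: float
    age: float
    sex: str
    bmi: float
    asa_ps: int
    procedure: str
    comorbidities: dict = field(default_factory=dict)
    pacu_los: float = float("nan")
    prolonged: bool | None = None

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.asa_ps not in ASA_LEVELS:
            raise ValueError(f"asa_ps must be in {ASA_LEVELS}, got {self.asa_ps!r}")
        if self.scheduled_duration <= 0:
            raise ValueError("scheduled_duration must be positive")
        missing = [f for f in COMORBIDITY_FLAGS if f not in self.comorbidities]
        if missing:
            raise ValueError(f"missing comorbidity flags: {missing}")


@dataclass
class FeatureMatrix:
    """Encoded design matrix plus aligned labels.

    ``X`` is indexed by case id; ``y`` shares that index (int 0/1).
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share an identical index")

    @property
    def case_ids(self) -> pd.Index:
        return self.X.index

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def subset(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.X.loc[ids], self.y.loc[ids])


@dataclass
class SplitResult:
    train: FeatureMatrix
    test: FeatureMatrix
    split_ratio: float
    seed: int


def compute_prolonged_threshold(los_values, quantile: float = 0.75) -> float:
    """Empirical quantile of PACU LOS (linear interpolation between order statistics).

    The pipeline's canonical outcome threshold is fixed at 180 min; this
    operation exists to verify/derive the threshold on a given cohort.
    """
    arr = np.asarray(los_values, dtype=float)
    if arr.size == 0:
        raise ValueError("los_values must be non-empty")
    if np.any(arr < 0):
        raise ValueError("PACU LOS values must be non-negative")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(arr, quantile))  # numpy default = linear interpolation


def label_prolonged(pacu_los: float, threshold: float = PROLONGED_THRESHOLD_MIN) -> bool:
    """True iff the stay is prolonged; the boundary is inclusive (>= threshold)."""
    if pacu_los < 0:
        raise ValueError(f"pacu_los must be non-negative, got {pacu_los}")
    return bool(pacu_los >= threshold)


def label_cases(cases, threshold: float = PROLONGED_THRESHOLD_MIN):
    """Set ``prolonged`` on every case in place; returns the cases."""
    for c in cases:
        c.prolonged = label_prolonged(c.pacu_los, threshold)
    return cases


def cases_to_frame(cases) -> pd.DataFrame:
    """Flatten cases into one row per case (comorbidities as 0/1 columns)."""
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "date": c.date.isoformat(),
            "surgeon_id": c.surgeon_id,
            "scheduled_start": c.scheduled_start,
            "scheduled_duration": c.scheduled_duration,
            "age": c.age,
            "sex": c.sex,
            "bmi": c.bmi,
            "asa_ps": c.asa_ps,
            "procedure": c.procedure,
            "pacu_los": c.pacu_los,
            "prolonged": int(c.prolonged) if c.prolonged is not None else "",
        }
        for flag in COMORBIDITY_FLAGS:
            row[flag] = int(c.comorbidities[flag])
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")


def frame_to_cases(frame: pd.DataFrame):
    """Inverse of :func:`cases_to_frame`."""
    cases = []
    for case_id, row in frame.iterrows():
        prolonged = row.get("prolonged", "")
        prolonged = None if prolonged in ("", None) or pd.isna(prolonged) else bool(int(prolonged))
        cases.append(
            PatientCase(
                case_id=str(case_id),
                date=Date.fromisoformat(str(row["date"])),
                surgeon_id=str(row["surgeon_id"]),
                scheduled_start=float(row["scheduled_start"]),
                scheduled_duration=float(row["scheduled_duration"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                asa_ps=int(row["asa_ps"]),
                procedure=str(row["procedure"]),
                comorbidities={f: bool(int(row[f])) for f in COMORBIDITY_FLAGS},
                pacu_los=float(row["pacu_los"]),
                prolonged=prolonged,
            )
        )
    return cases


def encode_features(cases, procedure_levels=None) -> FeatureMatrix:
    """One-hot encode categorical features into a deterministic design matrix.

    Column order: the three numeric features, then sex, ASA, procedure
    one-hot groups (sorted levels), then the 16 comorbidity flags.  Numeric
    features pass through unscaled; scaling, where a model family needs it,
    is that family's concern.

    Parameters
    ----------
    procedure_levels
        Fixed procedure vocabulary.  Defaults to the sorted levels observed
        in ``cases``.  An unseen level raises a ``ValueError`` naming it.
    """
    if not cases:
        raise ValueError("cases must be non-empty")
    if procedure_levels is None:
        procedure_levels = sorted({c.procedure for c in cases})
    else:
        procedure_levels = list(procedure_levels)
        unseen = sorted({c.procedure for c in cases} - set(procedure_levels))
        if unseen:
            raise ValueError(f"unseen procedure level(s) at encode time: {unseen}")

    data = {}
    data["age"] = [c.age for c in cases]
    data["bmi"] = [c.bmi for c in cases]
    data["scheduled_duration"] = [c.scheduled_duration for c in cases]
    for lvl in SEX_LEVELS:
        data[f"sex_{lvl}"] = [1.0 if c.sex == lvl else 0.0 for c in cases]
    for lvl in ASA_LEVELS:
        data[f"asa_{lvl}"] = [1.0 if c.asa_ps == lvl else 0.0 for c in cases]
    for lvl in procedure_levels:
        data[f"procedure_{lvl}"] = [1.0 if c.procedure == lvl else 0.0 for c in cases]
    for flag in COMORBIDITY_FLAGS:
        data[flag] = [1.0 if c.comorbidities[flag] else 0.0 for c in cases]

    index = pd.Index([c.case_id for c in cases], name="case_id")
    X = pd.DataFrame(data, index=index, dtype=float)
    y = pd.Series(
        [int(c.prolonged) if c.prolonged is not None else 0 for c in cases],
        index=index,
        name="prolonged",
        dtype=int,
    )
    return FeatureMatrix(X, y)


def decode_features(matrix: FeatureMatrix) -> pd.DataFrame:
    """Recover categorical fields from the one-hot columns (round-trip check)."""
    X = matrix.X
    out = pd.DataFrame(index=X.index)
    for fam, levels in (("sex", SEX_LEVELS), ("asa", ASA_LEVELS)):
        cols = [f"{fam}_{lvl}" for lvl in levels]
        out[fam] = [levels[i] for i in np.argmax(X[cols].to_numpy(), axis=1)]
    proc_cols = [c for c in X.columns if c.startswith("procedure_")]
    levels = [c[len("procedure_"):] for c in proc_cols]
    out["procedure"] = [levels[i] for i in np.argmax(X[proc_cols].to_numpy(), axis=1)]
    for flag in COMORBIDITY_FLAGS:
        out[flag] = X[flag].to_numpy() > 0.5
    return out


def split_train_test(matrix: FeatureMatrix, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Label-stratified random split of encoded cases (deterministic given seed)."""
    if matrix.n_rows < 10:
        raise ValueError("need at least 10 rows to split")
    counts = matrix.y.value_counts()
    if len(counts) < 2:
        raise ValueError("both outcome classes must be present to split")
    train_ids, test_ids = train_test_split(
        matrix.case_ids,
        train_size=ratio,
        stratify=matrix.y,
        random_state=seed,
        shuffle=True,
    )
    return SplitResult(
        train=matrix.subset(train_ids),
        test=matrix.subset(test_ids),
        split_ratio=ratio,
        seed=seed,
    )
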