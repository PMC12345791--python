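"""Delta-feature response classification: forward selection + SVM-RBF.

Non-responder (NR) is the positive class throughout.  Class scores follow
the convention: positive score => predicted non-responder; a score of
exactly zero predicts responder (the majority class).  Scores with
``|score| < margin`` are flagged as lying in an indeterminate zone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .texture import FEATURE_NAMES, DeltaFeatureSet

POSITIVE_LABEL = "NR"
NEGATIVE_LABEL = "R"

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    delta: DeltaFeatureSet
    true_label: str | None = None  # "R" / "NR"

    def __post_init__(self) -> None:
        if self.true_label is not None and self.true_label not in ("R", "NR"):
            raise ValueError(f"invalid label {self.true_label!r}")


@dataclass(frozen=True)
class PredictionResult:
    patient_id: str
    class_score: float
    predicted_label: str
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.class_score):
            raise ValueError("class score must be finite")
        expected = POSITIVE_LABEL if self.class_score > 0 else NEGATIVE_LABEL
        if self.predicted_label != expected:
            raise ValueError("predicted_label inconsistent with class_score sign")


def records_to_frame(records: Sequence[PatientRecord]) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(
        [r.delta.as_series() for r in records],
        index=[r.patient_id for r in records],
    )
    y = pd.Series([r.true_label for r in records], index=X.index, name="true_label")
    return X, y


def _as_xy(
    records_or_X, y=None
) -> tuple[pd.DataFrame, np.ndarray]:
    if y is None:
        X, y = records_to_frame(records_or_X)
    else:
        X = records_or_X
    y = np.asarray(y)
    return X, y


def _make_pipeline(C: float, gamma, class_weight) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)),
        ]
    )


def sequential_feature_selection(
    records_or_X,
    k: int,
    y=None,
    *,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    class_weight="balanced",
) -> list[str]:
    """Greedy forward selection maximising cross-validated balanced accuracy.

    At each step every remaining feature is tried in combination with the
    current selection; the feature with the highest stratified-CV balanced
    accuracy is added (ties broken by schema order).  Deterministic given
    the records and ``seed``.
    """
    X, yv = _as_xy(records_or_X, y)
    classes = np.unique(yv)
    if classes.size < 2:
        raise ValueError("feature selection requires both classes present")
    if not 0 <= k <= X.shape[1]:
        raise ValueError(f"k must lie in [0, {X.shape[1]}]")
    if k == 0:
        return []
    n_min = min(np.sum(yv == c) for c in classes)
    folds = min(cv_folds, int(n_min))
    if folds < 2:
        raise ValueError("need at least 2 records per class")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    selected: list[str] = []
    remaining = list(X.columns)
    ybin = (yv == POSITIVE_LABEL).astype(int)
    for _ in range(k):
        best_name, best_score = None, -np.inf
        for name in remaining:
            cols = selected + [name]
            model = _make_pipeline(C, gamma, class_weight)
            scores = cross_val_score(
                model, X[cols].to_numpy(), ybin, cv=cv, scoring="balanced_accuracy"
            )
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best_name, best_score = name, score
        assert best_name is not None
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


@dataclass
class ResponseModel:
    """Trained SVM-RBF on standardised selected delta features.

    Holds the training matrix so the model can be serialised as plain JSON
    and reconstructed bit-identically by refitting.
    """

    selected_features: list[str]
    C: float
    gamma: float | str
    class_weight: str | dict | None
    X_train: np.ndarray  # (n, k) raw (unstandardised) selected features
    y_train: np.ndarray  # 1 = NR, 0 = R
    indeterminate_margin: float = 0.0
    _scaler: StandardScaler = field(default=None, repr=False)  # type: ignore[assignment]
    _svc: SVC = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.y_train = np.asarray(self.y_train, dtype=int)
        if self._scaler is None:
            self._fit()

    def _fit(self) -> None:
        self._scaler = StandardScaler().fit(self.X_train)
        Xs = self._scaler.transform(self.X_train)
        self._svc = SVC(
            kernel="rbf", C=self.C, gamma=self.gamma, class_weight=self.class_weight
        ).fit(Xs, self.y_train)

    # -- scoring ----------------------------------------------------------
    def decision_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise KeyError(f"missing selected features: {missing}")
            X = X[self.selected_features].to_numpy()
        X = np.asarray(X, dtype=float)
        # classes_ = [0, 1]; positive decision value => class 1 (NR)
        return self._svc.decision_function(self._scaler.transform(X))

    @property
    def standardization(self) -> dict[str, np.ndarray]:
        return {"centre": self._scaler.mean_.copy(), "scale": self._scaler.scale_.copy()}

    # -- serialisation ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format": "qusr-response-model-v1",
            "selected_features": self.selected_features,
            "C": self.C,
            "gamma": self.gamma,
            "class_weight": self.class_weight,
            "indeterminate_margin": self.indeterminate_margin,
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ResponseModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "qusr-response-model-v1":
            raise ValueError("unrecognised model archive")
        return cls(
            selected_features=payload["selected_features"],
            C=payload["C"],
            gamma=payload["gamma"],
            class_weight=payload["class_weight"],
            X_train=np.array(payload["X_train"]),
            y_train=np.array(payload["y_train"]),
            indeterminate_margin=payload["indeterminate_margin"],
        )


def train_svm(
    records_or_X,
    selected_features: Sequence[str],
    y=None,
    *,
    C: float | None = None,
    gamma=None,
    cv_folds: int = 5,
    seed: int = 0,
    class_weight="balanced",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    indeterminate_margin: float = 0.0,
) -> ResponseModel:
    """Fit the SVM-RBF on the selected delta features.

    When ``C``/``gamma`` are not given they are chosen by stratified
    cross-validated grid search (balanced accuracy).  Standardisation is
    fitted on the training records only.
    """
    X, yv = _as_xy(records_or_X, y)
    if np.unique(yv).size < 2:
        raise ValueError("training requires both classes present")
    missing = [f for f in selected_features if f not in X.columns]
    if missing:
        raise KeyError(f"missing selected features: {missing}")
    Xs = X[list(selected_features)].to_numpy(dtype=float)
    degenerate = [
        f for f, s in zip(selected_features, Xs.std(axis=0)) if not s > 0
    ]
    if degenerate:
        raise ValueError(f"zero-variance selected feature(s): {degenerate}")
    ybin = (yv == POSITIVE_LABEL).astype(int)

    if C is None or gamma is None:
        n_min = int(min(np.sum(ybin == 0), np.sum(ybin == 1)))
        folds = max(2, min(cv_folds, n_min))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        best = (-np.inf, None, None)
        for c_try in C_grid if C is None else [C]:
            for g_try in gamma_grid if gamma is None else [gamma]:
                model = _make_pipeline(c_try, g_try, class_weight)
                score = float(
                    np.mean(
                        cross_val_score(model, Xs, ybin, cv=cv, scoring="balanced_accuracy")
                    )
                )
                if score > best[0] + 1e-12:
                    best = (score, c_try, g_try)
        C, gamma = best[1], best[2]

    return ResponseModel(
        selected_features=list(selected_features),
        C=float(C),
        gamma=gamma,
        class_weight=class_weight,
        X_train=Xs,
        y_train=ybin,
        indeterminate_margin=indeterminate_margin,
    )


def predict(model: ResponseModel, record: PatientRecord) -> PredictionResult:
    """Score one patient; positive score => NR, zero-ties => R."""
    X = pd.DataFrame([record.delta.as_series()], index=[record.patient_id])
    score = float(model.decision_scores(X)[0])
    label = POSITIVE_LABEL if score > 0 else NEGATIVE_LABEL
    return PredictionResult(
        patient_id=record.patient_id,
        class_score=score,
        predicted_label=label,
        indeterminate=abs(score) < model.indeterminate_margin,
    )


def predict_table(model: ResponseModel, X: pd.DataFrame) -> pd.DataFrame:
    """Score a delta-feature table; returns patient_id-indexed predictions."""
    scores = model.decision_scores(X)
    labels = np.where(scores > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame(
        {
            "class_score": scores,
            "predicted_label": labels,
            "indeterminate": np.abs(scores) < model.indeterminate_margin,
        },
        index=X.index,
    )
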