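"""Classifier registry, cross-validation, evaluation and persistence.

Thirteen classical classifier families are registered; each entry builds a
fresh scikit-learn (or XGBoost) estimator from a seed plus optional
hyperparameter overrides.  The positive class (label 1) is cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import __version__
from .errors import FeatureMismatchError, StratificationError, UnknownClassifierError
from .metrics import MetricSet, mean_metrics, score_predictions

DEFAULT_THRESHOLD = 0.5


def _build_registry() -> Dict[str, callable]:
    return {
        "random_forest": lambda seed, **kw: RandomForestClassifier(
            random_state=seed, **kw
        ),
        "gradient_boosting": lambda seed, **kw: GradientBoostingClassifier(
            random_state=seed, **kw
        ),
        "xgboost": lambda seed, **kw: XGBClassifier(
            random_state=seed, eval_metric="logloss", **kw
        ),
        "decision_tree": lambda seed, **kw: DecisionTreeClassifier(
            random_state=seed, **kw
        ),
        "mlp": lambda seed, **kw: MLPClassifier(
            random_state=seed, max_iter=500, **kw
        ),
        "svc_linear": lambda seed, **kw: SVC(
            kernel="linear", probability=True, random_state=seed, **kw
        ),
        "svc_rbf": lambda seed, **kw: SVC(
            kernel="rbf", probability=True, random_state=seed, **kw
        ),
        "gaussian_nb": lambda seed, **kw: GaussianNB(**kw),
        "qda": lambda seed, **kw: QuadraticDiscriminantAnalysis(**kw),
        "adaboost": lambda seed, **kw: AdaBoostClassifier(random_state=seed, **kw),
        "knn": lambda seed, **kw: KNeighborsClassifier(**kw),
        "logistic_regression": lambda seed, **kw: LogisticRegression(
            random_state=seed, max_iter=2000, **kw
        ),
        "gaussian_process": lambda seed, **kw: GaussianProcessClassifier(
            random_state=seed, **kw
        ),
    }


REGISTRY = _build_registry()
REGISTRY_ORDER = list(REGISTRY)


@dataclass(frozen=True)
class ClassifierSpec:
    """A registry key plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def build(self, seed: int):
        if self.name not in REGISTRY:
            raise UnknownClassifierError(
                f"unknown classifier {self.name!r}; registry has {REGISTRY_ORDER}"
            )
        return REGISTRY[self.name](seed, **self.hyperparameters)


@dataclass
class TrainedModel:
    """A fitted estimator bundled with everything prediction needs."""

    estimator: object
    spec: ClassifierSpec
    feature_names: List[str]
    seed: int
    threshold: float = DEFAULT_THRESHOLD
    feature_families: Optional[List[str]] = None
    version: str = __version__

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for each row; validates feature names."""
        if list(X.columns) != self.feature_names:
            raise FeatureMismatchError(
                "feature names of input do not match the model's training features"
            )
        return self.estimator.predict_proba(X.to_numpy())[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.scores(X) >= self.threshold).astype(int)


@dataclass
class CVResult:
    """Five per-fold metric sets and their mean for one classifier spec."""

    spec: ClassifierSpec
    folds: List[MetricSet]
    mean: MetricSet
    seed: int


def _as_xy(X: pd.DataFrame, y: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def five_fold_cv(
    X: pd.DataFrame, y: Sequence[int], spec: ClassifierSpec, seed: int = 42, n_folds: int = 5
) -> CVResult:
    """Stratified k-fold cross-validation (default 5 folds).

    Each class needs at least *n_folds* members so every fold contains both
    classes.
    """
    Xa, ya = _as_xy(X, y)
    counts = np.bincount(ya, minlength=2)
    if counts.min() < n_folds:
        raise StratificationError(
            f"each class needs >= {n_folds} members for {n_folds}-fold CV; got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: List[MetricSet] = []
    for train_idx, test_idx in skf.split(Xa, ya):
        est = spec.build(seed)
        est.fit(Xa[train_idx], ya[train_idx])
        scores = est.predict_proba(Xa[test_idx])[:, 1]
        folds.append(score_predictions(ya[test_idx], scores))
    return CVResult(spec=spec, folds=folds, mean=mean_metrics(folds), seed=seed)


def train_evaluate(
    train_X: pd.DataFrame,
    train_y: Sequence[int],
    val_X: pd.DataFrame,
    val_y: Sequence[int],
    spec: ClassifierSpec,
    seed: int = 42,
    threshold: float = DEFAULT_THRESHOLD,
) -> Tuple[TrainedModel, MetricSet]:
    """Fit on the training set and score the hold-out validation set."""
    if list(train_X.columns) != list(val_X.columns):
        raise FeatureMismatchError("train and validation feature names differ")
    Xa, ya = _as_xy(train_X, train_y)
    if len(np.unique(ya)) < 2:
        raise StratificationError("training set must contain both classes")
    est = spec.build(seed)
    est.fit(Xa, ya)
    model = TrainedModel(
        estimator=est,
        spec=spec,
        feature_names=list(train_X.columns),
        seed=seed,
        threshold=threshold,
    )
    metrics = score_predictions(np.asarray(val_y, dtype=int), model.scores(val_X), threshold)
    return model, metrics


def select_best(
    results: Sequence[Tuple[ClassifierSpec, MetricSet]]
) -> Tuple[ClassifierSpec, MetricSet]:
    """Best candidate by validation AUC, ties by MCC, then input order."""
    if not results:
        raise ValueError("no candidates to select from")
    best = results[0]
    for cand in results[1:]:
        b_auc = -1.0 if best[1].auc is None else best[1].auc
        c_auc = -1.0 if cand[1].auc is None else cand[1].auc
        if (c_auc, cand[1].mcc) > (b_auc, best[1].mcc):
            best = cand
    return best


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model (joblib archive with metadata)."""
    joblib.dump(
        {
            "estimator": model.estimator,
            "spec": {"name": model.spec.name, "hyperparameters": model.spec.hyperparameters},
            "feature_names": model.feature_names,
            "seed": model.seed,
            "threshold": model.threshold,
            "feature_families": model.feature_families,
            "version": model.version,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        estimator=payload["estimator"],
        spec=ClassifierSpec(payload["spec"]["name"], payload["spec"]["hyperparameters"]),
        feature_names=payload["feature_names"],
        seed=payload["seed"],
        threshold=payload["threshold"],
        feature_families=payload.get("feature_families"),
        version=payload.get("version", "unknown"),
    )
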