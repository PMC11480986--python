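"""Model training under the holdout / cross-validation protocol.

The protocol: records are split once into an 80% model-building set and
a 20% holdout test set; the holdout set plays no role in model building
and is only used for external validation.  The building set is subject
to 5-fold cross-validation, and grid search over a hyperparameter grid
picks the configuration with the best mean CV score (R^2 for
regression, ROC AUC for binary, negative log loss for the 3-category
task).  The winning configuration is refit on the full building set.

Three open estimator families are provided (regularized linear,
random-forest ensemble, gradient-boosted ensemble); which family wins
for a given dataset is a configuration choice, not a fidelity claim.
Feature selection, when requested, runs inside each CV training fold
(via a sklearn Pipeline) so validation folds never leak into it.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import clone
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.feature_selection import (
    SelectFromModel,
    SelectKBest,
    f_classif,
    f_regression,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from . import validation

# LightGBM auto-names sparse columns at fit time; the mismatch warning on
# later ndarray input is noise for anonymous fragment columns
import warnings  # noqa: E402

warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")


class MinSupportFilter(BaseEstimator, TransformerMixin):
    """Drop descriptor columns present in fewer than ``min_support`` fitted rows.

    Fitting happens on whatever rows the enclosing pipeline is fit on —
    a CV training fold or the building set — so support thresholds are
    never informed by validation or holdout rows.
    """

    def __init__(self, min_support: int = 2):
        self.min_support = min_support

    def fit(self, X, y=None):
        colsum = np.asarray(np.abs(X).sum(axis=0)).ravel()
        self.support_mask_ = colsum >= self.min_support
        if not self.support_mask_.any():
            raise ValueError("no fragments above support threshold")
        return self

    def transform(self, X):
        return X[:, self.support_mask_]

    def get_support(self):
        return self.support_mask_

TASKS = ("regression", "binary", "ternary")
FAMILIES = ("linear", "random_forest", "gradient_boosting")


class LeakageError(RuntimeError):
    """Raised when evaluation rows overlap the training rows."""


@dataclass
class SplitPlan:
    """One 80/20 holdout split plus a k-fold partition of the building set."""

    ids: list[str]
    holdout_indices: np.ndarray
    building_indices: np.ndarray
    fold_of_building: np.ndarray  # fold in 1..k, aligned with building_indices
    k: int
    seed: int
    stratified: bool

    @property
    def holdout_ids(self) -> list[str]:
        return [self.ids[i] for i in self.holdout_indices]

    @property
    def building_ids(self) -> list[str]:
        return [self.ids[i] for i in self.building_indices]

    @property
    def fold_assignment(self) -> dict[str, int]:
        return {self.ids[i]: int(f)
                for i, f in zip(self.building_indices, self.fold_of_building)}

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) row indices for one CV fold, in dataset coordinates."""
        mask = self.fold_of_building == fold
        return self.building_indices[~mask], self.building_indices[mask]


def make_split(
    ids: Sequence[str],
    strat_values=None,
    holdout_fraction: float = 0.2,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
    task: str = "regression",
) -> SplitPlan:
    """Deterministic stratified 80/20 + k-fold split plan.

    Classification tasks stratify on the class label; regression
    stratifies on pIC50 quartile.  Raises if any stratum has fewer than
    ``k`` members (it could not appear in every fold).
    """
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    strata = None
    if stratify and strat_values is not None:
        sv = np.asarray(strat_values)
        if task == "regression":
            # quartile strata, degrading to fewer bins if one is too small
            for q in (4, 3, 2):
                cand = pd.qcut(sv.astype(float), q=q, labels=False,
                               duplicates="drop")
                if np.bincount(cand).min() >= k:
                    strata = cand
                    break
        else:
            strata = sv
            classes, counts = np.unique(strata, return_counts=True)
            for c, cnt in zip(classes, counts):
                if cnt < k:
                    raise ValueError(f"stratum {c!r} has {cnt} < k={k} members")
    idx = np.arange(n)
    building, holdout = train_test_split(
        idx, test_size=holdout_fraction, random_state=seed,
        stratify=strata if strata is not None else None, shuffle=True,
    )
    building = np.sort(building)
    holdout = np.sort(holdout)
    if strata is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = splitter.split(building, np.asarray(strata)[building])
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = splitter.split(building)
    fold_of = np.zeros(len(building), dtype=int)
    for f, (_, val) in enumerate(fold_iter, start=1):
        fold_of[val] = f
    return SplitPlan(list(ids), holdout, building, fold_of, k, seed,
                     strata is not None)


@dataclass
class ModelSpec:
    task: str
    estimator_family: str = "linear"
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    feature_selection: tuple | str = "none"  # "none" | ("top_m", m) | "model_based"
    min_support: int = 0  # >0 adds an in-fold column support filter
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.estimator_family not in FAMILIES:
            raise ValueError(f"unknown estimator family {self.estimator_family!r}")
        if not self.hyperparameter_grid:
            self.hyperparameter_grid = default_grid(self.task, self.estimator_family)

    def with_grid(self, grid: dict[str, list]) -> "ModelSpec":
        return replace(self, hyperparameter_grid=grid)


def default_grid(task: str, family: str) -> dict[str, list]:
    if family == "linear":
        if task == "regression":
            return {"estimator__alpha": [0.1, 1.0, 10.0, 100.0]}
        return {"estimator__C": [0.01, 0.1, 1.0, 10.0]}
    if family == "random_forest":
        return {"estimator__n_estimators": [200],
                "estimator__min_samples_leaf": [1, 3]}
    return {"estimator__n_estimators": [200],
            "estimator__max_depth": [3, 6]}


def _base_estimator(task: str, family: str, random_state: int):
    if family == "linear":
        if task == "regression":
            return Ridge(alpha=1.0, random_state=random_state)
        return LogisticRegression(max_iter=2000, random_state=random_state)
    if family == "random_forest":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(n_estimators=200, random_state=random_state, n_jobs=1)
    cls = LGBMRegressor if task == "regression" else LGBMClassifier
    return cls(n_estimators=200, learning_rate=0.1, random_state=random_state,
               n_jobs=1, verbose=-1)


def build_pipeline(spec: ModelSpec) -> Pipeline:
    steps = []
    if spec.min_support > 0:
        steps.append(("support", MinSupportFilter(spec.min_support)))
    fs = spec.feature_selection
    if fs not in ("none", None):
        if isinstance(fs, (tuple, list)) and fs[0] == "top_m":
            score = f_regression if spec.task == "regression" else f_classif
            steps.append(("select", SelectKBest(score, k=int(fs[1]))))
        elif fs == "model_based":
            base = (ExtraTreesRegressor if spec.task == "regression"
                    else ExtraTreesClassifier)(
                n_estimators=50, random_state=spec.random_state, n_jobs=1)
            steps.append(("select", SelectFromModel(base)))
        else:
            raise ValueError(f"unknown feature_selection {fs!r}")
    steps.append(("estimator", _base_estimator(spec.task, spec.estimator_family,
                                               spec.random_state)))
    return Pipeline(steps)


@dataclass
class TrainedModel:
    pipeline: Pipeline
    spec: ModelSpec
    split_plan: SplitPlan
    cv_records: list[dict]
    best_params: dict
    best_cv_score: float
    selected_feature_indices: np.ndarray
    training_ids: list[str]
    n_features_in: int = 0
    vocabulary: object | None = None

    @property
    def classes_(self):
        return self.pipeline.named_steps["estimator"].classes_


@dataclass
class PredictionSet:
    ids: list[str]
    task: str
    values: np.ndarray  # predicted pIC50 (regression) or hard labels
    probabilities: np.ndarray | None = None  # classification only
    classes: np.ndarray | None = None
    ad_warnings: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids})
        if self.task == "regression":
            df["pic50_predicted"] = self.values
        else:
            df["label_predicted"] = self.values
            for j, c in enumerate(self.classes):
                df[f"p_class_{c}"] = self.probabilities[:, j]
        if self.ad_warnings is not None:
            df["ad_warning"] = self.ad_warnings
        return df


def _normalize_proba(P) -> np.ndarray:
    """Cast to float64 and renormalize float32 round-off in probability rows."""
    P = np.asarray(P, dtype=np.float64)
    return P / P.sum(axis=1, keepdims=True)


def _fold_score(task: str, estimator, X_val, y_val) -> float:
    if task == "regression":
        return validation.regression_metrics(y_val, estimator.predict(X_val)).r2
    P = _normalize_proba(estimator.predict_proba(X_val))
    if task == "binary":
        return validation.roc_auc(y_val, P[:, list(estimator.classes_).index(1)])
    classes = estimator.classes_
    onehot = (np.asarray(y_val)[:, None] == classes[None, :]).astype(float)
    return -validation.multiclass_log_loss(onehot, P)


def grid_search_train(X, y, spec: ModelSpec, split_plan: SplitPlan) -> TrainedModel:
    """Grid search with the plan's CV folds; refit the best point on the building set.

    Scores: R^2 (regression), AUC (binary), -log loss (ternary).  Ties
    break toward the earlier grid point, so results are reproducible for
    a fixed seed.
    """
    y = np.asarray(y)
    build = split_plan.building_indices
    if np.unique(y[build]).size < 2:
        raise ValueError("no variance in target")
    grid = list(ParameterGrid(spec.hyperparameter_grid))
    cv_records = []
    best_i, best_score = 0, -np.inf
    for gi, params in enumerate(grid):
        fold_scores = []
        for fold in range(1, split_plan.k + 1):
            tr, va = split_plan.fold_indices(fold)
            est = clone(build_pipeline(spec)).set_params(**params)
            # errstate: univariate F-scores on constant binary columns hit
            # sqrt-of-negative cancellation; sklearn maps the NaNs to -inf
            with np.errstate(invalid="ignore"):
                est.fit(X[tr], y[tr])
            fold_scores.append(_fold_score(spec.task, est, X[va], y[va]))
        mean_score = float(np.mean(fold_scores))
        cv_records.append({"params": params, "fold_scores": fold_scores,
                           "mean_score": mean_score})
        if mean_score > best_score:
            best_i, best_score = gi, mean_score
    final = clone(build_pipeline(spec)).set_params(**grid[best_i])
    with np.errstate(invalid="ignore"):
        final.fit(X[build], y[build])
    selected = np.arange(X.shape[1])
    if "support" in final.named_steps:
        selected = selected[final.named_steps["support"].get_support()]
    if "select" in final.named_steps:
        selected = selected[final.named_steps["select"].get_support()]
    return TrainedModel(final, spec, split_plan, cv_records, grid[best_i],
                        best_score, selected, split_plan.building_ids,
                        n_features_in=X.shape[1])


def predict(model: TrainedModel, X_new, ids: Sequence[str] | None = None) -> PredictionSet:
    """Apply a trained model; classification reports probabilities and hard labels.

    Binary labels use probability threshold 0.5; the 3-category label is
    the argmax class, with ties broken toward the lower category index.
    """
    if model.n_features_in and X_new.shape[1] != model.n_features_in:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features_in} "
            f"columns, got {X_new.shape[1]}")
    rid = list(ids) if ids is not None else [str(i) for i in range(X_new.shape[0])]
    if model.spec.task == "regression":
        return PredictionSet(rid, "regression", model.pipeline.predict(X_new))
    P = _normalize_proba(model.pipeline.predict_proba(X_new))
    classes = model.classes_
    if model.spec.task == "binary":
        j = list(classes).index(1)
        labels = (P[:, j] >= 0.5).astype(int)
    else:
        labels = classes[np.argmax(P, axis=1)]  # argmax takes the first max
    return PredictionSet(rid, model.spec.task, labels, P, classes)


def evaluate_holdout(model: TrainedModel, X_hold, y_hold,
                     ids: Sequence[str] | None = None):
    """Task-appropriate metric bundle on the holdout set; guards against leakage."""
    if ids is not None:
        overlap = set(ids) & set(model.training_ids)
        if overlap:
            raise LeakageError(f"holdout ids overlap training set: {sorted(overlap)[:5]}")
    preds = predict(model, X_hold, ids)
    y = np.asarray(y_hold)
    if model.spec.task == "regression":
        return validation.regression_metrics(y, preds.values)
    if model.spec.task == "binary":
        counts = validation.confusion_counts(y, preds.values)
        m = validation.binary_metrics(counts)
        j = list(preds.classes).index(1)
        m.auc = validation.roc_auc(y, preds.probabilities[:, j])
        return m
    return validation.multiclass_metrics(y, preds.values, preds.probabilities,
                                         classes=preds.classes)


def save_model(model: TrainedModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "estimator.pkl", "wb") as fh:
        pickle.dump(model.pipeline, fh)
    meta = {
        "task": model.spec.task,
        "estimator_family": model.spec.estimator_family,
        "hyperparameter_grid": model.spec.hyperparameter_grid,
        "feature_selection": model.spec.feature_selection,
        "min_support": model.spec.min_support,
        "random_state": model.spec.random_state,
        "best_params": model.best_params,
        "best_cv_score": model.best_cv_score,
        "selected_feature_indices": model.selected_feature_indices.tolist(),
        "n_features_in": model.n_features_in,
        "training_ids": model.training_ids,
        "seed": model.split_plan.seed,
        "cv_records": model.cv_records,
    }
    with open(d / "model.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    with open(d / "estimator.pkl", "rb") as fh:
        pipeline = pickle.load(fh)
    with open(d / "model.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    fs = meta["feature_selection"]
    spec = ModelSpec(meta["task"], meta["estimator_family"],
                     meta["hyperparameter_grid"],
                     tuple(fs) if isinstance(fs, list) else fs,
                     meta.get("min_support", 0),
                     meta["random_state"])
    plan = SplitPlan(meta["training_ids"], np.array([], dtype=int),
                     np.arange(len(meta["training_ids"])),
                     np.zeros(len(meta["training_ids"]), dtype=int),
                     5, meta["seed"], False)
    return TrainedModel(pipeline, spec, plan, meta["cv_records"],
                        meta["best_params"], meta["best_cv_score"],
                        np.array(meta["selected_feature_indices"], dtype=int),
                        meta["training_ids"],
                        n_features_in=int(meta.get("n_features_in", 0)))
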