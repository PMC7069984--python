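"""Stratified cross-validation with AUC-driven grid search.

A small registry of probability-scoring classifiers (penalised logistic
regression, distance-weighted k-NN, Gaussian naive Bayes, CART tree,
random forest, gradient-boosted trees, optionally SVM and a one-layer
neural network) is tuned by exhaustive grid search over a shared stratified
k-fold assignment, scoring each grid point by the mean out-of-fold AUC.

Preprocessing (standardisation) is part of the per-fold pipeline, so test
folds never contribute to the scaler statistics.  Grid values must be
listed from the most regularised / simplest setting to the least; ties in
mean AUC keep the earlier (simpler) grid point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "FittedModel",
    "REGISTRY",
    "default_spec",
    "stratified_folds",
    "fit_classifier",
    "predict_scores",
    "auc",
    "grid_search",
]


def _mk_lasso(params, seed):
    return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                              max_iter=5000, random_state=seed, **params)


def _mk_ridge(params, seed):
    return LogisticRegression(l1_ratio=0.0, solver="liblinear",
                              max_iter=5000, random_state=seed, **params)


def _mk_knn(params, seed):
    return KNeighborsClassifier(weights="distance", **params)


def _mk_nb(params, seed):
    return GaussianNB(**params)


def _mk_cart(params, seed):
    return DecisionTreeClassifier(random_state=seed, **params)


def _mk_rf(params, seed):
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def _mk_gbt(params, seed):
    return GradientBoostingClassifier(random_state=seed, **params)


def _mk_svm(params, seed):
    # margin scores are mapped monotonically to [0, 1]; AUC is rank-based,
    # so the particular monotone link is immaterial
    return SVC(random_state=seed, probability=False, **params)


def _mk_nnet(params, seed):
    from sklearn.neural_network import MLPClassifier
    return MLPClassifier(random_state=seed, max_iter=1500, **params)


@dataclass(frozen=True)
class _RegistryEntry:
    factory: Any
    standardise: bool
    linear: bool
    default_grid: Mapping[str, tuple]


# grids list values simplest / most regularised first (tie-break order)
_C_GRID = tuple(float(c) for c in np.logspace(-3, 2, 10))

REGISTRY: dict[str, _RegistryEntry] = {
    "lasso": _RegistryEntry(_mk_lasso, True, True, {"C": _C_GRID}),
    "ridge": _RegistryEntry(_mk_ridge, True, True, {"C": _C_GRID}),
    "knn": _RegistryEntry(_mk_knn, True, False,
                          {"n_neighbors": (50, 20, 10, 5)}),
    "naive_bayes": _RegistryEntry(_mk_nb, False, False,
                                  {"var_smoothing": (1e-6, 1e-8, 1e-9)}),
    "cart": _RegistryEntry(_mk_cart, False, False,
                           {"min_samples_leaf": (50, 20, 10),
                            "max_depth": (3, 5, 8)}),
    "random_forest": _RegistryEntry(_mk_rf, False, False,
                                    {"n_estimators": (300,),
                                     "max_features": ("sqrt", 0.3)}),
    "gbt": _RegistryEntry(_mk_gbt, False, False,
                          {"n_estimators": (100, 200),
                           "max_depth": (2, 3)}),
    "svm": _RegistryEntry(_mk_svm, True, False,
                          {"C": (0.01, 0.1, 1.0), "kernel": ("rbf",)}),
    "nnet": _RegistryEntry(_mk_nnet, True, False,
                           {"alpha": (1.0, 0.1),
                            "hidden_layer_sizes": ((8,), (16,))}),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A registry method plus its hyperparameter grid."""

    method: str
    grid: Mapping[str, tuple] = field(default_factory=dict)
    standardise: bool | None = None

    def __post_init__(self) -> None:
        if self.method not in REGISTRY:
            raise ValueError(f"unknown method {self.method!r}; registered: "
                             f"{sorted(REGISTRY)}")
        if any(len(tuple(v)) == 0 for v in self.grid.values()):
            raise ValueError("empty grid dimension")

    @property
    def entry(self) -> _RegistryEntry:
        return REGISTRY[self.method]

    @property
    def effective_grid(self) -> dict[str, tuple]:
        grid = {k: tuple(v) for k, v in self.entry.default_grid.items()}
        grid.update({k: tuple(v) for k, v in self.grid.items()})
        return grid

    @property
    def effective_standardise(self) -> bool:
        if self.standardise is None:
            return self.entry.standardise
        return self.standardise

    def grid_points(self) -> list[dict]:
        grid = self.effective_grid
        keys = list(grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(grid[k] for k in keys))]


def default_spec(method: str) -> ClassifierSpec:
    return ClassifierSpec(method=method)


@dataclass
class FittedModel:
    """A fitted pipeline that scores new rows by column name."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    method: str

    @property
    def is_linear(self) -> bool:
        return REGISTRY[self.method].linear

    @property
    def coefficients(self) -> pd.Series:
        """Per-feature coefficients of a linear method (scaled inputs)."""
        if not self.is_linear:
            raise ValueError(f"{self.method} exposes no coefficients; use "
                             "feature importances instead")
        est = self.pipeline.named_steps["clf"]
        return pd.Series(est.coef_.ravel(), index=list(self.feature_names))

    @property
    def importances(self) -> pd.Series | None:
        est = self.pipeline.named_steps["clf"]
        imp = getattr(est, "feature_importances_", None)
        if imp is None:
            return None
        return pd.Series(imp, index=list(self.feature_names))


@dataclass
class CVResult:
    """Grid-search outcome on one fold assignment."""

    method: str
    fold_assignment: np.ndarray
    fold_aucs: np.ndarray
    best_params: dict
    oof_scores: np.ndarray
    fold_coefs: pd.DataFrame | None      # features x folds (linear methods)
    fold_importances: pd.DataFrame | None
    grid_mean_aucs: dict
    failures: list

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "best_params": self.best_params,
            "n_failures": len(self.failures),
        }


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Assign each row to one of ``k`` stratified folds (deterministic).

    Per-fold positive counts differ by at most one from proportional
    allocation.  Requires both classes present and ``k`` at most the
    smaller class count.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smaller class count ({counts.min()})")
    splitter = StratifiedKFold(n_splits=k, shuffle=True,
                               random_state=int(seed) % (2 ** 32 - 1))
    assignment = np.empty(y.shape[0], dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
        assignment[test_idx] = fold
    return assignment


def _make_pipeline(spec: ClassifierSpec, params: dict, seed: int) -> Pipeline:
    steps = []
    if spec.effective_standardise:
        steps.append(("scaler", StandardScaler()))
    steps.append(("clf", spec.entry.factory(dict(params), seed)))
    return Pipeline(steps)


def fit_classifier(spec: ClassifierSpec, params: dict, X: pd.DataFrame, y,
                   seed: int = 0) -> FittedModel:
    """Fit one registry method at a fixed hyperparameter setting."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("outcome is degenerate (single class)")
    pipe = _make_pipeline(spec, params, seed)
    pipe.fit(X.to_numpy(dtype=float), y)
    return FittedModel(pipeline=pipe, feature_names=tuple(X.columns),
                       method=spec.method)


def predict_scores(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Probability-like scores in [0, 1]; columns must match training."""
    if tuple(X.columns) != model.feature_names:
        missing = set(model.feature_names) - set(X.columns)
        extra = set(X.columns) - set(model.feature_names)
        raise ValueError(
            f"feature columns do not match training columns "
            f"(missing: {sorted(missing)}, extra: {sorted(extra)}, "
            f"or wrong order)")
    arr = X.to_numpy(dtype=float)
    pipe = model.pipeline
    if hasattr(pipe.named_steps["clf"], "predict_proba"):
        return pipe.predict_proba(arr)[:, 1]
    return expit(pipe.decision_function(arr))


def auc(y, scores) -> float:
    """Area under the ROC curve (ties counted 1/2, Mann-Whitney identity)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined for a single-class outcome")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def grid_search(X: pd.DataFrame, y, spec: ClassifierSpec,
                folds: np.ndarray, seed: int = 0) -> CVResult:
    """Evaluate every grid point on the shared folds; keep the best.

    The best point maximises the mean fold AUC; exact ties keep the
    earlier point in grid order (grids are ordered simplest-first).  A
    grid point whose fit fails on any fold is recorded and discarded.
    """
    y = np.asarray(y)
    folds = np.asarray(folds)
    points = spec.grid_points()
    if not points:
        raise ValueError("empty hyperparameter grid")
    fold_ids = np.unique(folds)
    arr_idx = {f: (folds != f, folds == f) for f in fold_ids}

    best: tuple[float, dict, np.ndarray] | None = None
    grid_mean_aucs: dict = {}
    failures: list = []
    for params in points:
        aucs = np.empty(fold_ids.size)
        try:
            for j, f in enumerate(fold_ids):
                train, test = arr_idx[f]
                model = fit_classifier(spec, params, X.loc[train],
                                       y[train], seed=seed)
                aucs[j] = auc(y[test], predict_scores(model, X.loc[test]))
        except Exception as err:  # noqa: BLE001 - recorded, point discarded
            failures.append({"params": params, "error": repr(err)})
            continue
        key = tuple(sorted(params.items()))
        grid_mean_aucs[key] = float(aucs.mean())
        if best is None or aucs.mean() > best[0]:
            best = (float(aucs.mean()), params, aucs.copy())
    if best is None:
        raise RuntimeError(
            f"all {len(points)} grid points failed: {failures}")

    _, best_params, fold_aucs = best
    # refit at the winning point to collect per-fold coefficients and
    # out-of-fold scores
    oof = np.empty(y.shape[0], dtype=float)
    coef_cols: dict[int, pd.Series] = {}
    imp_cols: dict[int, pd.Series] = {}
    for f in fold_ids:
        train, test = arr_idx[f]
        model = fit_classifier(spec, best_params, X.loc[train], y[train],
                               seed=seed)
        oof[test] = predict_scores(model, X.loc[test])
        if model.is_linear:
            coef_cols[int(f)] = model.coefficients
        elif model.importances is not None:
            imp_cols[int(f)] = model.importances
    fold_coefs = pd.DataFrame(coef_cols) if coef_cols else None
    fold_imps = pd.DataFrame(imp_cols) if imp_cols else None
    return CVResult(method=spec.method, fold_assignment=folds,
                    fold_aucs=fold_aucs, best_params=dict(best_params),
                    oof_scores=oof, fold_coefs=fold_coefs,
                    fold_importances=fold_imps,
                    grid_mean_aucs=grid_mean_aucs, failures=failures)
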