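"""Incremental feature-selection wrapper driven by model reliance.

Starting from the full feature set, each iteration (1) re-tunes the
classifier by grid search under stratified k-fold cross-validation,
(2) refits it at the winning hyperparameters on the full data, (3) scores
the model reliance of every current feature, and (4) retains exactly the
features with reliance strictly above the cutoff (default 1).  The loop
terminates when no feature exceeds the cutoff, when the retained set
equals the current set (fixed point), or when the retained set is empty
(treated like the first case, with the previous iteration's model as the
final model).  Feature sets shrink strictly until termination, so the
procedure halts after at most ``|F| + 1`` iterations.

Dropped features never return (the procedure is greedy by design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed_sequence
from .cv import ClassifierSpec, CVResult, fit_classifier, grid_search, \
    stratified_folds
from .reliance import MRTable, loss, reliance_table

__all__ = [
    "IFSConfig",
    "IterationRecord",
    "IterationTrace",
    "select_retained",
    "run_ifs",
    "best_iteration",
]

#: termination reasons recorded on the final iteration
REASON_ALL_BELOW = "all_mr_at_or_below_cutoff"
REASON_FIXED_POINT = "fixed_point"
REASON_MAX_ITER = "max_iterations"
REASON_FAILURE = "classifier_failure"


@dataclass(frozen=True)
class IFSConfig:
    k: int = 10
    n_repeats: int = 10
    loss_kind: str = "one_minus_auc"
    mr_cutoff: float = 1.0
    mr_on: str = "refit"          # "refit" (full-data model) or "oof"
    max_iterations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mr_on not in {"refit", "oof"}:
            raise ValueError("mr_on must be 'refit' or 'oof'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class IterationRecord:
    index: int
    features: tuple[str, ...]
    best_params: dict
    fold_aucs: tuple[float, ...]
    mr_table: MRTable | None
    cv: CVResult
    termination: str | None = None

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


@dataclass
class IterationTrace:
    spec: ClassifierSpec
    config: IFSConfig
    records: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final(self) -> IterationRecord:
        return self.records[-1]

    def feature_path(self) -> list[tuple[str, ...]]:
        return [rec.features for rec in self.records]

    def to_jsonable(self) -> dict:
        return {
            "method": self.spec.method,
            "config": {
                "k": self.config.k, "n_repeats": self.config.n_repeats,
                "loss_kind": self.config.loss_kind,
                "mr_cutoff": self.config.mr_cutoff,
                "mr_on": self.config.mr_on, "seed": self.config.seed,
            },
            "iterations": [
                {
                    "index": rec.index,
                    "n_features": rec.n_features,
                    "features": list(rec.features),
                    "best_params": rec.best_params,
                    "mean_auc": rec.mean_auc,
                    "sd_auc": rec.sd_auc,
                    "fold_aucs": list(rec.fold_aucs),
                    "termination": rec.termination,
                }
                for rec in self.records
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=1)


def select_retained(mr_table: MRTable, cutoff: float = 1.0) -> list[str]:
    """Features with reliance strictly above ``cutoff``.

    The inequality is strict: a feature with MR exactly at the cutoff is
    dropped.  Infinite (flagged) reliances are always retained.
    """
    return [s.feature for s in mr_table if s.mr > cutoff]


def _iteration_seed(config: IFSConfig, what: str, i: int) -> int:
    state = child_seed_sequence(config.seed, what, str(i)).generate_state(1)
    return int(state[0] >> 1)  # keep below 2**31


def _oof_reliance(spec, best_params, X, y, folds, config, i) -> MRTable:
    """Out-of-fold variant: permuted columns are scored through the
    per-fold models that never saw the corresponding rows."""
    from .cv import predict_scores
    from .reliance import MRScore
    from ._rng import child_rng

    y = np.asarray(y)
    fold_ids = np.unique(folds)
    models = {}
    for f in fold_ids:
        train = folds != f
        models[f] = fit_classifier(spec, best_params, X.loc[train], y[train],
                                   seed=_iteration_seed(config, "fit", i))

    def oof_scores(data: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(data), dtype=float)
        for f in fold_ids:
            test = folds == f
            out[test] = predict_scores(models[f], data.loc[test])
        return out

    e_orig = loss(y, oof_scores(X), config.loss_kind)
    scores = []
    n = len(X)
    for feat in X.columns:
        rng = child_rng(config.seed, "mr-oof", str(i), feat)
        col = X[feat].to_numpy().copy()
        work = X.copy()
        e_perm = []
        for _ in range(config.n_repeats):
            work[feat] = col[rng.permutation(n)]
            e_perm.append(loss(y, oof_scores(work), config.loss_kind))
        e_perm_mean = float(np.mean(e_perm))
        scores.append(MRScore(feature=feat, e_orig=float(e_orig),
                              e_perm=tuple(map(float, e_perm)),
                              n_repeats=config.n_repeats,
                              infinite=e_orig == 0.0 and e_perm_mean > 0.0))
    return MRTable(scores=scores)


def run_ifs(X: pd.DataFrame, y, spec: ClassifierSpec,
            config: IFSConfig | None = None) -> IterationTrace:
    """Run the wrapper to termination; the trace records every iteration."""
    if config is None:
        config = IFSConfig()
    y = np.asarray(y)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")

    trace = IterationTrace(spec=spec, config=config)
    current = tuple(X.columns)
    i = 1
    while True:
        Xi = X[list(current)]
        folds = stratified_folds(y, config.k,
                                 seed=_iteration_seed(config, "folds", i))
        try:
            cv = grid_search(Xi, y, spec, folds,
                             seed=_iteration_seed(config, "fit", i))
            model = fit_classifier(spec, cv.best_params, Xi, y,
                                   seed=_iteration_seed(config, "fit", i))
            if config.mr_on == "refit":
                mrt = reliance_table(
                    model, Xi, y, kind=config.loss_kind,
                    n_repeats=config.n_repeats,
                    seed=_iteration_seed(config, "mr", i))
            else:
                mrt = _oof_reliance(spec, cv.best_params, Xi, y, folds,
                                    config, i)
        except Exception as err:  # noqa: BLE001 - trace truncated, reason kept
            trace.records.append(IterationRecord(
                index=i, features=current, best_params={}, fold_aucs=(),
                mr_table=None, cv=None,
                termination=f"{REASON_FAILURE}: {err!r}"))
            return trace

        record = IterationRecord(
            index=i, features=current, best_params=cv.best_params,
            fold_aucs=tuple(float(a) for a in cv.fold_aucs),
            mr_table=mrt, cv=cv)
        trace.records.append(record)

        retained = select_retained(mrt, config.mr_cutoff)
        if not retained:
            record.termination = REASON_ALL_BELOW
            return trace
        if tuple(retained) == current or set(retained) == set(current):
            record.termination = REASON_FIXED_POINT
            return trace
        if config.max_iterations is not None and i >= config.max_iterations:
            record.termination = REASON_MAX_ITER
            return trace
        current = tuple(f for f in current if f in set(retained))
        i += 1


def best_iteration(trace: IterationTrace, criterion: str = "max_auc",
                   delta: float = 0.02) -> int:
    """Pick an iteration index (1-based) from a completed trace.

    ``max_auc``  -- the iteration with the highest mean AUC; ties go to the
    iteration with fewer features.
    ``parsimony`` -- the iteration with the smallest feature set whose mean
    AUC is within ``delta`` of the best; ties go to the higher AUC.
    """
    records = [r for r in trace.records if r.fold_aucs]
    if not records:
        raise ValueError("trace has no completed iterations")
    if criterion == "max_auc":
        return min(records, key=lambda r: (-r.mean_auc, r.n_features)).index
    if criterion == "parsimony":
        best_auc = max(r.mean_auc for r in records)
        eligible = [r for r in records if r.mean_auc >= best_auc - delta]
        return min(eligible, key=lambda r: (r.n_features, -r.mean_auc)).index
    raise ValueError(f"unknown criterion {criterion!r}")
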