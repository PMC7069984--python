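"""Model reliance: permutation-based feature importance as an error ratio.

For a fitted model, target vector ``y``, data ``X`` and loss ``L``, the
reliance of the model on feature ``f`` is the ratio of the model error
after randomly permuting the values of ``f`` to the error on the intact
data::

    MR(f) = E[L(y, model(X with f permuted))] / L(y, model(X))

A value above 1 means permuting ``f`` degrades the model, i.e. the model
relies on the feature.  The permutation expectation is estimated by
averaging over ``n_repeats`` independent permutations (default 10); the
identity permutation is allowed among the draws, which keeps the estimate
unbiased.

The loss is configurable: ``one_minus_auc`` (default, aligning the loss
with the AUC tuning metric), ``log_loss`` or ``misclassification``.  When
the original error is exactly zero, MR is defined as 1 if the permuted
error is also zero and as +inf otherwise (carried with an explicit flag;
+inf sorts above any finite reliance when selecting features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .cv import FittedModel, auc, predict_scores

__all__ = [
    "MRScore",
    "MRTable",
    "LOSS_KINDS",
    "permute_feature",
    "loss",
    "model_reliance",
    "reliance_table",
]

LOSS_KINDS = ("one_minus_auc", "log_loss", "misclassification")

_LOG_EPS = 1e-15


def loss(y, scores, kind: str = "one_minus_auc") -> float:
    """Non-negative model error of probability scores against binary ``y``."""
    if kind not in LOSS_KINDS:
        raise ValueError(f"unknown loss kind {kind!r}; choose from {LOSS_KINDS}")
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    if kind == "one_minus_auc":
        return 1.0 - auc(y, s)
    if kind == "log_loss":
        p = np.clip(s, _LOG_EPS, 1.0 - _LOG_EPS)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return float(np.mean((s >= 0.5).astype(float) != y))


def permute_feature(X: pd.DataFrame, f: str, seed: int) -> pd.DataFrame:
    """Return a copy of ``X`` with column ``f`` uniformly permuted.

    The permutation is ``numpy.random.default_rng(seed).permutation(len(X))``
    applied to the column's values; all other columns are untouched and the
    multiset of ``f``'s values is preserved.
    """
    if f not in X.columns:
        raise KeyError(f"unknown feature {f!r}")
    out = X.copy()
    perm = np.random.default_rng(seed).permutation(len(X))
    out[f] = out[f].to_numpy()[perm]
    return out


@dataclass(frozen=True)
class MRScore:
    feature: str
    e_orig: float
    e_perm: tuple[float, ...]
    n_repeats: int
    infinite: bool

    @property
    def e_perm_mean(self) -> float:
        return float(np.mean(self.e_perm))

    @property
    def mr(self) -> float:
        if self.e_orig > 0.0:
            # permutations that leave the loss unchanged give a ratio of
            # exactly 1, free of summation round-off
            if all(e == self.e_orig for e in self.e_perm):
                return 1.0
            return self.e_perm_mean / self.e_orig
        return float("inf") if self.infinite else 1.0


@dataclass
class MRTable:
    scores: list[MRScore]

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": [s.feature for s in self.scores],
            "e_orig": [s.e_orig for s in self.scores],
            "e_perm_mean": [s.e_perm_mean for s in self.scores],
            "mr": [s.mr for s in self.scores],
            "n_repeats": [s.n_repeats for s in self.scores],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _reliance_from_scores(model: FittedModel, X: pd.DataFrame, y,
                          f: str, kind: str, n_repeats: int,
                          rng: np.random.Generator,
                          e_orig: float) -> MRScore:
    col = X[f].to_numpy().copy()
    work = X.copy()
    e_perm = []
    n = len(X)
    for _ in range(n_repeats):
        work[f] = col[rng.permutation(n)]
        e_perm.append(loss(y, predict_scores(model, work), kind))
    e_perm_mean = float(np.mean(e_perm))
    infinite = e_orig == 0.0 and e_perm_mean > 0.0
    return MRScore(feature=f, e_orig=float(e_orig),
                   e_perm=tuple(float(e) for e in e_perm),
                   n_repeats=n_repeats, infinite=infinite)


def model_reliance(model: FittedModel, X: pd.DataFrame, y, f: str,
                   kind: str = "one_minus_auc", n_repeats: int = 10,
                   seed: int = 0) -> MRScore:
    """Estimate the model reliance on feature ``f``.

    ``e_orig`` is computed once on the unpermuted data; the permuted error
    is averaged over ``n_repeats`` independent permutations drawn from
    ``numpy.random.default_rng(seed)``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if f not in X.columns:
        raise KeyError(f"unknown feature {f!r}")
    e_orig = loss(y, predict_scores(model, X), kind)
    rng = np.random.default_rng(seed)
    return _reliance_from_scores(model, X, y, f, kind, n_repeats, rng, e_orig)


def reliance_table(model: FittedModel, X: pd.DataFrame, y,
                   features=None, kind: str = "one_minus_auc",
                   n_repeats: int = 10, seed: int = 0) -> MRTable:
    """Model reliance for each feature, with independent permutation
    streams per feature derived from ``(seed, feature name)``."""
    if features is None:
        features = list(X.columns)
    features = list(features)
    unknown = set(features) - set(X.columns)
    if unknown:
        raise KeyError(f"features not in X: {sorted(unknown)}")
    if not features:
        return MRTable(scores=[])
    e_orig = loss(y, predict_scores(model, X), kind)
    scores = []
    for f in features:
        rng = child_rng(seed, "mr", f)
        scores.append(_reliance_from_scores(model, X, y, f, kind,
                                            n_repeats, rng, e_orig))
    return MRTable(scores=scores)
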