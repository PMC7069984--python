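"""Report surfaces: threshold metrics, coefficient stability, baseline
characteristics, and classifier-by-iteration performance grids."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .cv import CVResult
from .features import tinnitus_status
from .wrapper import IterationTrace

__all__ = [
    "MetricsAtThreshold",
    "metrics_at_threshold",
    "coefficient_stability",
    "baseline_table",
    "PerformanceGrid",
    "performance_matrix",
    "DEFAULT_BASELINE_VARIABLES",
]


@dataclass(frozen=True)
class MetricsAtThreshold:
    """Confusion counts and derived proportions at a probability threshold.

    A score exactly at the threshold counts as a positive prediction
    (>= rule).  Ratios with a zero denominator are undefined and reported
    as NaN, never as 0.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "npv": self.npv,
        }


def metrics_at_threshold(y, scores, threshold: float = 0.5
                         ) -> MetricsAtThreshold:
    """Confusion metrics of probability scores dichotomised at ``threshold``."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = s >= threshold
    pos = y == 1
    return MetricsAtThreshold(
        threshold=float(threshold),
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)))


def coefficient_stability(cv: CVResult) -> pd.DataFrame:
    """Median, MAD and inclusion count of coefficients across folds.

    Works for linear methods only.  The MAD is the unscaled median
    absolute deviation (no consistency factor); inclusion counts the folds
    with a nonzero coefficient.
    """
    if cv.fold_coefs is None:
        raise ValueError(
            f"{cv.method} exposes no per-fold coefficients; use the stored "
            "fold importances for tree-based methods instead")
    coefs = cv.fold_coefs
    med = coefs.median(axis=1)
    mad = (coefs.sub(med, axis=0)).abs().median(axis=1)
    inclusion = (coefs != 0.0).sum(axis=1)
    return pd.DataFrame({
        "median_coef": med, "mad": mad,
        "inclusion": inclusion.astype(np.int64),
    })


#: (display name, cohort column/derivation, kind, test) rows for the
#: baseline table; kind is "continuous" or "categorical"
DEFAULT_BASELINE_VARIABLES = (
    ("Age in years", "age", "continuous", "TT"),
    ("Tinnitus duration in years", "tindur", "continuous", "MW"),
    ("Days until start of treatment", "days_to_treatment", "continuous", "MW"),
    ("Male sex", "sex", "categorical", "Chi"),
    ("TQ total score", "tq_total", "continuous", "TT"),
    ("PSQ total score", "psq_total", "continuous", "TT"),
    ("ADSL depression score", "adsl_sum_t0", "continuous", "MW"),
)


def _p_continuous(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "TT":
        return float(stats.ttest_ind(a, b).pvalue)
    if test == "MW":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r} for a continuous variable")


def baseline_table(cohort: CohortTable, grouping=None,
                   variables=DEFAULT_BASELINE_VARIABLES) -> pd.DataFrame:
    """Two-group comparison of baseline characteristics.

    ``grouping`` is a binary vector (default: tinnitus status at the TQ
    distress cutoff).  Continuous variables are summarised as mean +/- SD
    per group and compared by unpaired two-tailed t-test (``TT``) or
    Mann-Whitney test (``MW``); categorical variables as n (%) with a
    chi-square test (``Chi``, without continuity correction).
    """
    df = cohort.data
    if grouping is None:
        grouping = tinnitus_status(df["tq_total"].to_numpy())
    grouping = np.asarray(grouping)
    if np.unique(grouping).size != 2:
        raise ValueError("grouping must have exactly two non-empty groups")
    g0, g1 = np.unique(grouping)
    in0, in1 = grouping == g0, grouping == g1

    rows = []
    for label, column, kind, test in variables:
        if kind == "continuous":
            a = df.loc[in0, column].to_numpy(dtype=float)
            b = df.loc[in1, column].to_numpy(dtype=float)
            rows.append({
                "variable": label,
                "group0": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                "group1": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "p_value": _p_continuous(a, b, test),
                "test": test,
            })
        elif kind == "categorical":
            if test != "Chi":
                raise ValueError("categorical variables use the Chi test")
            values = df[column].astype(str)
            contingency = pd.crosstab(values, grouping)
            chi2, p, _, _ = stats.chi2_contingency(contingency.to_numpy(),
                                                   correction=False)
            top = values.value_counts().index[0]
            n0 = int(((values == top) & in0).sum())
            n1 = int(((values == top) & in1).sum())
            rows.append({
                "variable": f"{label} ({top})",
                "group0": f"{n0} ({100 * n0 / in0.sum():.0f}%)",
                "group1": f"{n1} ({100 * n1 / in1.sum():.0f}%)",
                "p_value": float(p),
                "test": test,
            })
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows)


@dataclass
class PerformanceGrid:
    """Classifier-by-iteration grid of cross-validation performance.

    ``auc`` and ``n_features`` are iteration-by-classifier frames with NaN
    where a wrapper had already terminated; ``best`` maps each classifier
    to the iteration index with the highest mean AUC.
    """

    auc: pd.DataFrame
    n_features: pd.DataFrame
    best: dict[str, int]

    def formatted(self) -> pd.DataFrame:
        out = {}
        for clf in self.auc.columns:
            col = []
            for i in self.auc.index:
                a = self.auc.loc[i, clf]
                if np.isnan(a):
                    col.append("—")
                else:
                    cell = f"{a:.3f} ({int(self.n_features.loc[i, clf])})"
                    if self.best[clf] == i:
                        cell = f"*{cell}"
                    col.append(cell)
            out[clf] = col
        return pd.DataFrame(out, index=self.auc.index)


def performance_matrix(traces) -> PerformanceGrid:
    """Assemble the performance grid from one trace per classifier."""
    if isinstance(traces, IterationTrace):
        traces = [traces]
    if isinstance(traces, dict):
        named = dict(traces)
    else:
        named = {}
        for t in traces:
            name = t.spec.method
            if name in named:  # disambiguate duplicate methods
                name = f"{name}_{sum(k.startswith(name) for k in named) + 1}"
            named[name] = t
    if not named:
        raise ValueError("need at least one trace")

    max_iter = max(len(t.records) for t in named.values())
    idx = pd.Index(range(1, max_iter + 1), name="iteration")
    auc = pd.DataFrame(np.nan, index=idx, columns=list(named))
    nfeat = pd.DataFrame(np.nan, index=idx, columns=list(named))
    best: dict[str, int] = {}
    for name, t in named.items():
        completed = [r for r in t.records if r.fold_aucs]
        for rec in completed:
            auc.loc[rec.index, name] = rec.mean_auc
            nfeat.loc[rec.index, name] = rec.n_features
        if completed:
            best[name] = max(completed,
                             key=lambda r: (r.mean_auc, -r.n_features)).index
    return PerformanceGrid(auc=auc, n_features=nfeat, best=best)
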