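"""Design-matrix assembly from raw questionnaire responses.

Turns a :class:`~tinndep.cohort.CohortTable` into the numeric feature
matrix and binary outcome used by the classifiers: ordinal items cast to
numeric, sub-scale and total scores recomputed from their items,
categorical fields one-hot encoded (full indicator set, no reference level
dropped), and the outcome dichotomised from the post-treatment depression
sum at the clinical cutoff of 16.

Patients with any missing response are excluded listwise (complete-case
design); there is no imputation path.  No feature column is ever derived
from a post-treatment (T1) response -- every column carries provenance
metadata and the assembler enforces this leakage guard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, CLINICAL_CUTOFF
from .schema import QuestionnaireSchema, ScaleRule, default_schema

__all__ = [
    "FeatureMatrix",
    "ExclusionLog",
    "exclude_incomplete",
    "one_hot",
    "score_scale",
    "dichotomize_depression",
    "tinnitus_status",
    "assemble_features",
    "OUTCOME_COLUMN",
    "TQ_DISTRESS_CUTOFF",
]

OUTCOME_COLUMN = "depression_status"

#: TQ total at or below which tinnitus counts as compensated
TQ_DISTRESS_CUTOFF = 46


@dataclass
class ExclusionLog:
    n_input: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded


@dataclass
class FeatureMatrix:
    """Numeric design matrix with named columns plus the binary outcome."""

    X: pd.DataFrame
    y: pd.Series
    provenance: dict[str, dict]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out[OUTCOME_COLUMN] = self.y.to_numpy()
        out.insert(0, CohortTable.ID_COLUMN, self.X.index)
        out.to_csv(path, index=False)

    def provenance_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        df = df.set_index(CohortTable.ID_COLUMN)
        y = df.pop(OUTCOME_COLUMN).astype(np.int64)
        return cls(X=df.astype(float), y=y, provenance={})


def exclude_incomplete(table: CohortTable) -> tuple[CohortTable, ExclusionLog]:
    """Drop every patient with at least one missing cell (listwise)."""
    mask = table.missing_mask().any(axis=1).to_numpy()
    log = ExclusionLog(n_input=table.n, n_excluded=int(mask.sum()))
    if log.n_retained == 0:
        raise ValueError("all patients excluded: every row has missing cells")
    kept = CohortTable(table.data.loc[~mask].reset_index(drop=True))
    return kept, log


def one_hot(values, field: str, levels, prefix: str = "") -> pd.DataFrame:
    """Expand a categorical vector into one indicator column per level.

    Column names follow ``{prefix}{field}_{level}``; each row has exactly
    one indicator set.  A value outside ``levels`` is rejected.
    """
    values = pd.Series(values).astype(object)
    levels = list(levels)
    unseen = set(values.unique()) - set(levels)
    if unseen:
        raise ValueError(
            f"value(s) {sorted(map(str, unseen))} of field {field!r} not in "
            f"declared levels {levels}")
    out = pd.DataFrame(
        {f"{prefix}{field}_{lvl}": (values == lvl).astype(float).to_numpy()
         for lvl in levels},
        index=values.index)
    return out


def score_scale(items, rule: ScaleRule,
                item_range: tuple[int, int]) -> np.ndarray:
    """Apply one scoring rule to an item matrix (columns = ``rule.items``).

    Additive rules return the plain (possibly reverse-coded) item sum;
    ``rescale01`` maps the sum to the unit interval; ``linear`` applies an
    affine transform of the sum.  Items outside the declared range are
    rejected.
    """
    lo, hi = item_range
    if isinstance(items, pd.DataFrame):
        mat = items[list(rule.items)].to_numpy(dtype=float)
    else:
        mat = np.asarray(items, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(rule.items):
            raise ValueError("item matrix shape does not match the rule")
    if np.isnan(mat).any():
        raise ValueError(f"scale {rule.name!r}: missing item responses")
    if mat.min() < lo or mat.max() > hi:
        raise ValueError(
            f"scale {rule.name!r}: item response outside range [{lo}, {hi}]")
    if rule.reverse:
        rev_idx = [rule.items.index(it) for it in rule.reverse]
        mat = mat.copy()
        mat[:, rev_idx] = lo + hi - mat[:, rev_idx]
    total = mat.sum(axis=1)
    n = len(rule.items)
    if rule.kind == "sum":
        return total
    if rule.kind == "rescale01":
        return (total - n * lo) / (n * (hi - lo))
    return rule.intercept + rule.slope * total


def _dichotomize(values, cutoff: int, upper: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.isnan(arr).any() or arr.min() < 0 or arr.max() > upper:
        raise ValueError(f"{what} score outside [0, {upper}]")
    out = (arr >= cutoff).astype(np.int64)
    return out[0] if scalar else out


def dichotomize_depression(adsl_sum):
    """Depression status from the ADSL sum: 0-15 subclinical (0), 16-60
    clinical (1)."""
    return _dichotomize(adsl_sum, CLINICAL_CUTOFF, 60, "depression")


def tinnitus_status(tq_total):
    """Tinnitus status from the TQ total: 0-46 compensated (0), 47-84
    decompensated (1)."""
    return _dichotomize(tq_total, TQ_DISTRESS_CUTOFF + 1, 84, "tinnitus")


def assemble_features(table: CohortTable,
                      schema: QuestionnaireSchema | None = None
                      ) -> FeatureMatrix:
    """Assemble the numeric design matrix and outcome from a complete table.

    Columns are, in schema order: every single item (numeric), every
    sub-scale/total score (recomputed from items), one indicator per
    categorical level, and the numeric covariates.  The outcome is the
    dichotomised T1 depression sum; no T1-derived column enters the
    feature block.
    """
    if schema is None:
        schema = default_schema()
    df = table.data
    if table.missing_mask().to_numpy().any():
        raise ValueError(
            "cohort table contains missing cells; run exclude_incomplete first")

    index = pd.Index(df[CohortTable.ID_COLUMN], name=CohortTable.ID_COLUMN)
    blocks: list[pd.DataFrame] = []
    provenance: dict[str, dict] = {}

    for ins in schema.instruments:
        items = df[list(ins.items)].astype(float)
        items.index = index
        lo, hi = ins.item_range
        if items.to_numpy().min() < lo or items.to_numpy().max() > hi:
            raise ValueError(
                f"{ins.name}: item response outside [{lo}, {hi}]")
        renamed = items.rename(columns={c: f"{ins.prefix}{c}"
                                        for c in ins.items})
        blocks.append(renamed)
        for col, src in zip(renamed.columns, ins.items):
            provenance[col] = {"instrument": ins.name, "kind": "item",
                               "source": [src], "timepoint": "t0"}
        for rule in ins.scales:
            col = f"{ins.prefix}{rule.name}"
            vals = score_scale(items, rule, ins.item_range)
            blocks.append(pd.DataFrame({col: vals}, index=index))
            provenance[col] = {"instrument": ins.name, "kind": "scale",
                               "source": list(rule.items), "timepoint": "t0"}

    for cat in schema.categoricals:
        enc = one_hot(df[cat.column], cat.name, cat.levels, prefix=cat.prefix)
        enc.index = index
        blocks.append(enc)
        instrument = cat.prefix.rstrip("_")
        for col, lvl in zip(enc.columns, cat.levels):
            provenance[col] = {"instrument": instrument, "kind": "one_hot",
                               "source": [cat.column], "level": str(lvl),
                               "timepoint": "t0"}

    for cov in schema.covariates:
        vals = df[cov.column].astype(float).to_numpy()
        blocks.append(pd.DataFrame({cov.feature_name: vals}, index=index))
        provenance[cov.feature_name] = {
            "instrument": cov.feature_name.split("_")[0], "kind": "numeric",
            "source": [cov.column], "timepoint": "t0"}

    X = pd.concat(blocks, axis=1)
    if X.columns.duplicated().any():
        dupes = sorted(X.columns[X.columns.duplicated()])
        raise ValueError(f"duplicate feature columns: {dupes}")

    # leakage guard: features must be pre-treatment only, by provenance
    bad = [c for c, meta in provenance.items() if meta["timepoint"] != "t0"]
    if bad or OUTCOME_COLUMN in X.columns:
        raise ValueError(f"post-treatment columns in feature block: {bad}")

    t1_items = df[[f"adsl_t1_{i:02d}" for i in range(1, 21)]].astype(float)
    adsl_sum_t1 = t1_items.sum(axis=1).to_numpy()
    y = pd.Series(dichotomize_depression(adsl_sum_t1), index=index,
                  name=OUTCOME_COLUMN)
    return FeatureMatrix(X=X, y=y, provenance=provenance)
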