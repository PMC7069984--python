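"""Declarative description of the questionnaire battery.

A :class:`QuestionnaireSchema` lists the instruments (item columns, item
ranges, scale-scoring rules), the categorical socio-demographic fields and
the numeric covariates.  The same schema object drives both cohort
simulation and design-matrix assembly, so the two can never drift apart.

The default schema describes a battery of seven instruments commonly used
in tinnitus outpatient settings:

* ADSL  -- 20-item general depression scale, items 0-3, additive sum 0-60,
  clinical cutoff at a sum of 16;
* PSQ   -- 30-item perceived stress questionnaire, items 1-4, sub-scale and
  total scores rescaled to the unit interval;
* SF8   -- 8-item general health survey with norm-like linear transforms;
* TQ    -- 52-item tinnitus questionnaire, items 0-2, total score 0-84 over
  the 42 scored items, distress cutoff at 46;
* TINSKAL -- three visual-analogue scales (loudness, frequency, distress);
* TLQ   -- tinnitus localisation (categorical) and quality items;
* SOZK  -- socio-demographics (one-hot fields plus numeric covariates).

Under the default schema the assembled design matrix has exactly 185
columns: every single item as a numeric feature, every sub-scale/total
score, and one indicator column per categorical level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

#: number of feature columns the default schema assembles
N_FEATURES_DEFAULT = 185


@dataclass(frozen=True)
class ScaleRule:
    """Scoring rule for a sub-scale or total score.

    ``kind`` is one of:

    * ``"sum"``       -- additive score over ``items`` (reverse-keyed items
      are re-coded as ``lo + hi - x`` before summing);
    * ``"rescale01"`` -- additive score mapped to [0, 1] as
      ``(sum - n*lo) / (n*(hi - lo))`` (PSQ convention);
    * ``"linear"``    -- affine transform ``intercept + slope * sum``
      (SF8 norm-like scores).
    """

    name: str
    items: tuple[str, ...]
    kind: str = "sum"
    reverse: tuple[str, ...] = ()
    intercept: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"sum", "rescale01", "linear"}:
            raise ValueError(f"unknown scoring kind {self.kind!r}")
        if not self.items:
            raise ValueError(f"scale {self.name!r} references no items")
        unknown = set(self.reverse) - set(self.items)
        if unknown:
            raise ValueError(f"reverse-keyed items not in scale: {sorted(unknown)}")


@dataclass(frozen=True)
class Instrument:
    """One questionnaire: item columns, shared item range, scoring rules."""

    name: str
    prefix: str
    items: tuple[str, ...]
    item_range: tuple[int, int]
    scales: tuple[ScaleRule, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.item_range
        if hi <= lo:
            raise ValueError(f"{self.name}: empty item range {self.item_range}")
        declared = set(self.items)
        for rule in self.scales:
            missing = set(rule.items) - declared
            if missing:
                raise ValueError(
                    f"{self.name}: scale {rule.name!r} references undeclared "
                    f"items {sorted(missing)}"
                )

    @property
    def n_features(self) -> int:
        return len(self.items) + len(self.scales)


@dataclass(frozen=True)
class CategoricalField:
    """A categorical column expanded to one indicator per level."""

    name: str
    column: str
    levels: tuple[str, ...]
    prefix: str

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"{self.name}: needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate levels")

    def feature_names(self) -> list[str]:
        return [f"{self.prefix}{self.name}_{lvl}" for lvl in self.levels]


@dataclass(frozen=True)
class NumericCovariate:
    column: str
    feature_name: str


@dataclass(frozen=True)
class QuestionnaireSchema:
    instruments: tuple[Instrument, ...]
    categoricals: tuple[CategoricalField, ...]
    covariates: tuple[NumericCovariate, ...] = ()

    def instrument(self, name: str) -> Instrument:
        for ins in self.instruments:
            if ins.name == name:
                return ins
        raise KeyError(name)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for ins in self.instruments:
            names.extend(f"{ins.prefix}{it}" for it in ins.items)
            names.extend(f"{ins.prefix}{rule.name}" for rule in ins.scales)
        for cat in self.categoricals:
            names.extend(cat.feature_names())
        names.extend(cov.feature_name for cov in self.covariates)
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())

    def item_columns(self) -> list[str]:
        cols: list[str] = []
        for ins in self.instruments:
            cols.extend(ins.items)
        return cols

    def validate(self) -> None:
        names = self.feature_names()
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "QuestionnaireSchema":
        with open(path) as fh:
            raw = json.load(fh)

        def _tup(seq):
            return tuple(seq)

        instruments = tuple(
            Instrument(
                name=i["name"],
                prefix=i["prefix"],
                items=_tup(i["items"]),
                item_range=tuple(i["item_range"]),
                scales=tuple(
                    ScaleRule(
                        name=s["name"],
                        items=_tup(s["items"]),
                        kind=s["kind"],
                        reverse=_tup(s["reverse"]),
                        intercept=s["intercept"],
                        slope=s["slope"],
                    )
                    for s in i["scales"]
                ),
            )
            for i in raw["instruments"]
        )
        categoricals = tuple(
            CategoricalField(
                name=c["name"], column=c["column"], levels=_tup(c["levels"]),
                prefix=c["prefix"],
            )
            for c in raw["categoricals"]
        )
        covariates = tuple(
            NumericCovariate(column=c["column"], feature_name=c["feature_name"])
            for c in raw.get("covariates", ())
        )
        return cls(instruments=instruments, categoricals=categoricals,
                   covariates=covariates)


def _items(stem: str, n: int) -> tuple[str, ...]:
    return tuple(f"{stem}{i:02d}" for i in range(1, n + 1))


def default_schema() -> QuestionnaireSchema:
    """The default 185-feature battery (see module docstring)."""
    adsl_items = _items("adsl", 20)
    adsl = Instrument(
        name="ADSL", prefix="ADSL_", items=adsl_items, item_range=(0, 3),
        scales=(
            ScaleRule("depressed_affect", adsl_items[0:7]),
            ScaleRule("positive_affect", adsl_items[7:11]),
            ScaleRule("somatic", adsl_items[11:18]),
            ScaleRule("interpersonal", adsl_items[18:20]),
            ScaleRule("adsl_sum", adsl_items),
        ),
    )

    psq_items = _items("psq", 30)
    psq_subscales = {
        "worries": psq_items[0:5],
        "tension": psq_items[5:10],
        "joy": psq_items[10:14],
        "demands": psq_items[14:18],
        "fears": psq_items[18:22],
        "overload": psq_items[22:26],
        "harassment": psq_items[26:30],
    }
    psq = Instrument(
        name="PSQ", prefix="PSQ_", items=psq_items, item_range=(1, 4),
        scales=tuple(
            ScaleRule(name, its, kind="rescale01")
            for name, its in psq_subscales.items()
        )
        + (ScaleRule("psq_sum", psq_items, kind="rescale01"),),
    )

    sf8_items = _items("sf", 8)
    sf8 = Instrument(
        name="SF8", prefix="SF8_", items=sf8_items, item_range=(0, 5),
        scales=(
            ScaleRule("gh", sf8_items, kind="linear", intercept=20.0, slope=0.9),
            ScaleRule("pcs", sf8_items[0:4], kind="linear", intercept=26.0, slope=2.0),
            ScaleRule("mcs", sf8_items[4:8], kind="linear", intercept=26.0, slope=2.0),
        ),
    )

    tq_items = _items("tq", 52)
    tq = Instrument(
        name="TQ", prefix="TQ_", items=tq_items, item_range=(0, 2),
        scales=(
            ScaleRule("emotional", tq_items[0:8]),
            ScaleRule("cognitive", tq_items[8:16]),
            ScaleRule("intrusiveness", tq_items[16:24]),
            ScaleRule("auditory", tq_items[24:31]),
            ScaleRule("sleep", tq_items[31:36]),
            ScaleRule("somatic", tq_items[36:42]),
            # total over the 42 scored items: range 0-84
            ScaleRule("tq_sum", tq_items[0:42]),
        ),
    )

    tinskal = Instrument(
        name="TINSKAL", prefix="TINSKAL_",
        items=("loudness", "frequency", "distress"), item_range=(0, 10),
    )

    tlq = Instrument(
        name="TLQ", prefix="TLQ_", items=_items("tlq", 15), item_range=(0, 3),
    )

    categoricals = (
        CategoricalField("loc", "tlq_loc",
                         ("left", "right", "both", "head", "outside"), "TLQ_"),
        CategoricalField("sex", "sex", ("F", "M"), "SOZK_"),
        CategoricalField("nationality", "nationality",
                         ("german", "other"), "SOZK_"),
        CategoricalField("graduation", "graduation",
                         ("none", "secondary", "vocational", "abitur",
                          "university", "other"), "SOZK_"),
        CategoricalField("job", "job",
                         ("employed", "self_employed", "unemployed",
                          "retired", "in_training", "homemaker", "other"),
                         "SOZK_"),
        CategoricalField("marital", "marital",
                         ("unmarried", "married", "divorced", "widowed",
                          "separated"), "SOZK_"),
        CategoricalField("partnership", "partnership", ("yes", "no"), "SOZK_"),
        CategoricalField("hearing_aid", "hearing_aid", ("yes", "no"), "SOZK_"),
    )

    covariates = (
        NumericCovariate("age", "SOZK_age"),
        NumericCovariate("tindur", "SOZK_tindur"),
        NumericCovariate("days_to_treatment", "SOZK_days_to_treatment"),
    )

    schema = QuestionnaireSchema(
        instruments=(adsl, psq, sf8, tq, tinskal, tlq),
        categoricals=categoricals,
        covariates=covariates,
    )
    schema.validate()
    assert schema.n_features == N_FEATURES_DEFAULT, schema.n_features
    return schema
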