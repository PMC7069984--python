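import numpy as np
import pandas as pd
import pytest

from oracles import row_sum

from tinndep import (
    CohortTable, GeneratorConfig, assemble_features, dichotomize_depression,
    exclude_incomplete, generate_cohort, inject_missingness, one_hot,
    score_scale, tinnitus_status, OUTCOME_COLUMN,
)
from tinndep.schema import (
    CategoricalField, Instrument, NumericCovariate, QuestionnaireSchema,
    ScaleRule,
)


class TestExclusion:
    def test_rows_with_missing_cells_are_dropped(self):
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(5)],
            "a": [1.0, 2.0, np.nan, 4.0, 5.0],
            "b": [1.0] * 5,
        })
        kept, log = exclude_incomplete(CohortTable(df))
        assert kept.n == 4
        assert log.n_excluded == 1
        assert log.n_retained == 4

    def test_complete_table_is_identity(self, small_cohort):
        kept, log = exclude_incomplete(small_cohort)
        assert log.n_excluded == 0
        assert kept.data.equals(small_cohort.data)

    def test_matches_brute_force_row_scan(self):
        table = generate_cohort(GeneratorConfig(n_patients=1490, seed=2))
        noisy = inject_missingness(table, 0.001, seed=2)
        kept, log = exclude_incomplete(noisy)
        expected = sum(
            1 for _, row in noisy.data.drop(columns="patient_id").iterrows()
            if not row.isna().any())
        assert kept.n == expected == log.n_retained

    def test_all_rows_excluded_raises(self, small_cohort):
        allgone = inject_missingness(small_cohort, 1.0, seed=0)
        with pytest.raises(ValueError, match="all patients excluded"):
            exclude_incomplete(allgone)


class TestOneHot:
    def test_single_value_encodes_one_indicator(self):
        out = one_hot(["M"], "sex", ["F", "M"], prefix="SOZK_")
        assert out.columns.tolist() == ["SOZK_sex_F", "SOZK_sex_M"]
        assert out.iloc[0].tolist() == [0.0, 1.0]

    def test_column_sums_equal_level_counts(self):
        values = ["a", "b", "a", "c", "a"]
        out = one_hot(values, "f", ["a", "b", "c"])
        assert out.sum().tolist() == [3.0, 1.0, 1.0]
        assert (out.sum(axis=1) == 1.0).all()

    def test_unseen_level_rejected(self):
        with pytest.raises(ValueError, match="'x'"):
            one_hot(["a", "x"], "f", ["a", "b"])


class TestScoreScale:
    adsl_rule = ScaleRule("adsl_sum", tuple(f"i{k}" for k in range(20)))

    def test_all_zero_items_sum_to_zero(self):
        items = np.zeros((3, 20))
        assert score_scale(items, self.adsl_rule, (0, 3)).tolist() == [0, 0, 0]

    def test_all_max_items_reach_documented_maximum(self):
        items = np.full((2, 20), 3)
        assert score_scale(items, self.adsl_rule, (0, 3)).tolist() == [60, 60]

    def test_matches_per_row_summation_oracle(self):
        rng = np.random.default_rng(7)
        items = rng.integers(0, 4, size=(50, 20))
        got = score_scale(items, self.adsl_rule, (0, 3))
        assert np.array_equal(got, row_sum(items))

    def test_reverse_keyed_items_are_recoded(self):
        rule = ScaleRule("s", ("a", "b"), reverse=("b",))
        items = np.array([[0, 0], [3, 3]])
        # b reversed: 0 -> 3, 3 -> 0
        assert score_scale(items, rule, (0, 3)).tolist() == [3, 3]

    def test_out_of_range_item_rejected(self):
        items = np.full((1, 20), 4)
        with pytest.raises(ValueError, match="outside range"):
            score_scale(items, self.adsl_rule, (0, 3))

    def test_rescale01_maps_to_unit_interval(self):
        rule = ScaleRule("s", ("a", "b"), kind="rescale01")
        items = np.array([[1, 1], [4, 4], [1, 4]])
        assert score_scale(items, rule, (1, 4)).tolist() == [0.0, 1.0, 0.5]


class TestCutoffs:
    @pytest.mark.parametrize("score,expected", [
        (0, 0), (15, 0), (16, 1), (60, 1),
    ])
    def test_depression_cutoff_boundaries(self, score, expected):
        assert dichotomize_depression(score) == expected

    @pytest.mark.parametrize("score,expected", [
        (0, 0), (46, 0), (47, 1), (84, 1),
    ])
    def test_tinnitus_cutoff_boundaries(self, score, expected):
        assert tinnitus_status(score) == expected

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_depression(61)
        with pytest.raises(ValueError):
            tinnitus_status(-1)


def _mini_schema():
    instrument = Instrument(
        name="ADSL", prefix="ADSL_", items=("adsl01", "adsl02"),
        item_range=(0, 3), scales=(ScaleRule("adsl_sum", ("adsl01", "adsl02")),))
    cat = CategoricalField("sex", "sex", ("F", "M"), "SOZK_")
    cov = NumericCovariate("age", "SOZK_age")
    return QuestionnaireSchema(instruments=(instrument,), categoricals=(cat,),
                               covariates=(cov,))


def _mini_table():
    return CohortTable(pd.DataFrame({
        "patient_id": ["P1", "P2", "P3"],
        "sex": ["F", "M", "F"],
        "age": [40.0, 50.0, 60.0],
        "adsl01": [0, 1, 3],
        "adsl02": [2, 0, 3],
        **{f"adsl_t1_{i:02d}": [1, 0, 1] for i in range(1, 21)},
    }))


class TestAssemble:
    def test_default_schema_yields_185_columns(self, small_features):
        assert small_features.n_features == 185

    def test_outcome_not_among_features(self, small_features):
        assert OUTCOME_COLUMN not in small_features.X.columns

    def test_every_feature_is_pre_treatment(self, small_features):
        assert all(m["timepoint"] == "t0"
                   for m in small_features.provenance.values())
        assert not any("t1" in c.lower() for c in small_features.X.columns)

    def test_one_hot_groups_sum_to_one_per_row(self, small_features, schema):
        for cat in schema.categoricals:
            cols = cat.feature_names()
            sums = small_features.X[cols].sum(axis=1)
            assert (sums == 1.0).all()

    def test_idempotent(self, small_cohort, schema):
        a = assemble_features(small_cohort, schema)
        b = assemble_features(small_cohort, schema)
        assert a.X.equals(b.X)
        assert a.y.equals(b.y)

    def test_mini_schema_matrix_matches_hand_computation(self):
        fm = assemble_features(_mini_table(), _mini_schema())
        expected = pd.DataFrame(
            {
                "ADSL_adsl01": [0.0, 1.0, 3.0],
                "ADSL_adsl02": [2.0, 0.0, 3.0],
                "ADSL_adsl_sum": [2.0, 1.0, 6.0],
                "SOZK_sex_F": [1.0, 0.0, 1.0],
                "SOZK_sex_M": [0.0, 1.0, 0.0],
                "SOZK_age": [40.0, 50.0, 60.0],
            },
            index=pd.Index(["P1", "P2", "P3"], name="patient_id"))
        pd.testing.assert_frame_equal(fm.X, expected)
        # T1 item sum is 20 per patient for P1/P3 and 0 for P2
        assert fm.y.tolist() == [1, 0, 1]

    def test_missing_cells_rejected(self, small_cohort):
        noisy = inject_missingness(small_cohort, 0.05, seed=1)
        with pytest.raises(ValueError, match="missing"):
            assemble_features(noisy)
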