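import math

import numpy as np
import pandas as pd
import pytest

from tinndep import (
    ClassifierSpec, GeneratorConfig, IFSConfig, baseline_table,
    coefficient_stability, generate_cohort, grid_search,
    make_planted_classification, metrics_at_threshold, performance_matrix,
    run_ifs, stratified_folds,
)
from tinndep.cv import CVResult


class TestMetricsAtThreshold:
    def test_perfect_scores_give_all_ones(self):
        y = [1, 0, 1, 0]
        m = metrics_at_threshold(y, [1.0, 0.0, 1.0, 0.0], 0.5)
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision,
                m.npv) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_confusion_arithmetic(self):
        # TP=3 FP=1 TN=4 FN=2
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.0]
        m = metrics_at_threshold(y, s, 0.5)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 4, 2)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.7)

    def test_score_exactly_at_threshold_counts_positive(self):
        m = metrics_at_threshold([1, 0], [0.5, 0.4], 0.5)
        assert m.tp == 1 and m.fp == 0

    def test_undefined_ratio_is_nan_not_zero(self):
        # no predicted positives -> precision undefined
        m = metrics_at_threshold([1, 0], [0.1, 0.2], 0.5)
        assert math.isnan(m.precision)
        assert m.accuracy == 0.5

    def test_count_level_consistency(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        m = metrics_at_threshold(y, s, 0.5)
        assert m.n == 200
        p, n_neg = (y == 1).sum(), (y == 0).sum()
        assert m.sensitivity * p + m.specificity * n_neg == \
            pytest.approx(m.tp + m.tn)
        assert m.accuracy == pytest.approx((m.tp + m.tn) / m.n, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_at_threshold([], [], 0.5)


def _cv_with_coefs(mat: np.ndarray) -> CVResult:
    coefs = pd.DataFrame(mat, index=[f"f{i}" for i in range(mat.shape[0])])
    return CVResult(method="lasso", fold_assignment=np.zeros(1),
                    fold_aucs=np.array([0.8]), best_params={},
                    oof_scores=np.zeros(1), fold_coefs=coefs,
                    fold_importances=None, grid_mean_aucs={}, failures=[])


class TestCoefficientStability:
    def test_identical_coefficients_have_zero_mad(self):
        cv = _cv_with_coefs(np.full((2, 10), 1.5))
        out = coefficient_stability(cv)
        assert (out["mad"] == 0.0).all()
        assert (out["median_coef"] == 1.5).all()
        assert (out["inclusion"] == 10).all()

    def test_all_zero_feature_has_zero_inclusion(self):
        mat = np.vstack([np.zeros(10), np.ones(10)])
        out = coefficient_stability(_cv_with_coefs(mat))
        assert out.loc["f0", "inclusion"] == 0
        assert out.loc["f0", "median_coef"] == 0.0

    def test_matches_hand_computed_median_and_mad(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 100.0]])
        out = coefficient_stability(_cv_with_coefs(vals))
        assert out.loc["f0", "median_coef"] == 3.0
        # |x - 3| = [2, 1, 0, 1, 97] -> median 1 (unscaled MAD)
        assert out.loc["f0", "mad"] == 1.0
        assert out.loc["f0", "inclusion"] == 5

    def test_non_linear_method_rejected(self):
        cv = _cv_with_coefs(np.ones((1, 2)))
        cv.fold_coefs = None
        with pytest.raises(ValueError, match="importances"):
            coefficient_stability(cv)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n_patients=600, seed=21))


class TestBaselineTable:
    def test_default_grouping_is_tinnitus_status(self, cohort):
        out = baseline_table(cohort)
        assert out["variable"].str.startswith("ADSL depression score").any()
        assert out["p_value"].between(0, 1).all()

    def test_identical_groups_give_p_near_one_for_t_test(self, cohort):
        df = cohort.data
        doubled = pd.concat([df, df], ignore_index=True)
        from tinndep.cohort import CohortTable
        grouping = np.repeat([0, 1], len(df))
        out = baseline_table(CohortTable(doubled), grouping=grouping,
                             variables=(("Age in years", "age",
                                         "continuous", "TT"),))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_chi_square_matches_closed_form_2x2(self):
        # groups of 100 each with level counts (50,50) vs (90,10)
        from tinndep.cohort import CohortTable
        values = ["a"] * 50 + ["b"] * 50 + ["a"] * 90 + ["b"] * 10
        df = pd.DataFrame({"patient_id": range(200), "sex": values})
        grouping = np.repeat([0, 1], 100)
        out = baseline_table(CohortTable(df), grouping=grouping,
                             variables=(("Sex", "sex", "categorical", "Chi"),))
        a, b, c, d = 50, 50, 90, 10
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        from scipy.stats import chi2 as chi2_dist
        expected_p = float(chi2_dist.sf(chi2, 1))
        assert out["p_value"].iloc[0] == pytest.approx(expected_p, rel=1e-10)

    def test_empty_group_rejected(self, cohort):
        with pytest.raises(ValueError, match="two"):
            baseline_table(cohort, grouping=np.zeros(cohort.n))


@pytest.fixture(scope="module")
def traces():
    X, y = make_planted_classification(n=150, n_signal=2, n_noise=4,
                                       beta=1.2, seed=3)
    config = IFSConfig(k=4, n_repeats=3, seed=0)
    lasso = run_ifs(X, y, ClassifierSpec("lasso", grid={"C": (0.05, 1.0)}),
                    config)
    cart = run_ifs(X, y, ClassifierSpec("cart",
                                        grid={"min_samples_leaf": (20,),
                                              "max_depth": (3,)}), config)
    return {"lasso": lasso, "cart": cart}


class TestPerformanceMatrix:
    def test_grid_shape_covers_longest_trace(self, traces):
        grid = performance_matrix(traces)
        assert set(grid.auc.columns) == {"lasso", "cart"}
        assert grid.auc.shape == grid.n_features.shape
        assert grid.auc.index[0] == 1

    def test_terminated_wrapper_leaves_trailing_cells_empty(self, traces):
        grid = performance_matrix(traces)
        for name, trace in traces.items():
            n_done = len(trace)
            col = grid.auc[name]
            assert col.iloc[:n_done].notna().all()
            assert col.iloc[n_done:].isna().all()

    def test_best_flags_equal_recomputed_argmax(self, traces):
        grid = performance_matrix(traces)
        for name, trace in traces.items():
            means = {r.index: np.mean(r.fold_aucs) for r in trace.records}
            assert means[grid.best[name]] == max(means.values())

    def test_single_trace_grid(self, traces):
        grid = performance_matrix([traces["lasso"]])
        assert list(grid.auc.columns) == ["lasso"]

    def test_formatted_grid_marks_empty_cells(self, traces):
        grid = performance_matrix(traces)
        text = grid.formatted()
        shorter = min(traces.values(), key=len)
        if len(shorter) < len(grid.auc):
            col = text[shorter.spec.method]
            assert "—" in set(col)
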