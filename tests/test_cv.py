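import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import pairwise_auc

from tinndep import (
    ClassifierSpec, auc, default_spec, fit_classifier, grid_search,
    predict_scores, stratified_folds,
)


class TestStratifiedFolds:
    def test_exact_divisibility_gives_one_positive_per_fold(self):
        y = np.array([1, 0] * 10)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert y[folds == f].sum() == 1
            assert (folds == f).sum() == 2

    def test_folds_partition_all_indices(self):
        y = (np.random.default_rng(0).random(137) < 0.4).astype(int)
        folds = stratified_folds(y, 10, seed=1)
        assert folds.shape == y.shape
        counts = np.bincount(folds, minlength=10)
        assert counts.sum() == y.size
        assert counts.min() > 0

    def test_proportional_allocation_of_positives(self):
        y = np.zeros(1490, dtype=int)
        y[:777] = 1
        folds = stratified_folds(y, 10, seed=2)
        per_fold_pos = {int(y[folds == f].sum()) for f in range(10)}
        assert per_fold_pos <= {77, 78}

    def test_deterministic_given_seed(self):
        y = np.array([1, 0] * 30)
        assert np.array_equal(stratified_folds(y, 5, seed=3),
                              stratified_folds(y, 5, seed=3))

    def test_k_larger_than_class_count_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="smaller class"):
            stratified_folds(y, 3, seed=0)


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, y.astype(float)) == 1.0

    def test_all_ties_give_half(self):
        y = np.array([0, 1, 0, 1])
        assert auc(y, np.full(4, 0.3)) == 0.5

    def test_worked_example(self):
        # pairs: (.9,.8)+, (.9,.1)+, (.7,.8)-, (.7,.1)+ -> 3/4
        assert auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.4])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 2 ** 31 - 1))
    def test_equals_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
        assert auc(y, scores) == pytest.approx(pairwise_auc(y, scores),
                                               abs=1e-12)


class TestFitPredict:
    def test_extreme_l1_penalty_zeroes_all_coefficients(self, toy_xy):
        X, y = toy_xy
        model = fit_classifier(default_spec("lasso"), {"C": 1e-6}, X, y)
        assert (model.coefficients == 0.0).all()

    def test_unpenalised_lasso_separates_separable_data(self, toy_xy):
        X, y = toy_xy
        model = fit_classifier(default_spec("lasso"), {"C": 1e6}, X, y)
        assert auc(y, predict_scores(model, X)) == 1.0

    def test_identical_fit_is_deterministic(self, toy_xy):
        X, y = toy_xy
        a = fit_classifier(default_spec("lasso"), {"C": 1.0}, X, y, seed=1)
        b = fit_classifier(default_spec("lasso"), {"C": 1.0}, X, y, seed=1)
        assert a.coefficients.equals(b.coefficients)

    def test_degenerate_outcome_rejected(self, toy_xy):
        X, _ = toy_xy
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(default_spec("lasso"), {"C": 1.0}, X,
                           np.ones(len(X)))

    def test_scores_in_unit_interval(self, toy_xy):
        X, y = toy_xy
        for method in ("lasso", "cart", "naive_bayes", "knn"):
            model = fit_classifier(default_spec(method), {}, X, y, seed=0)
            s = predict_scores(model, X)
            assert s.min() >= 0.0 and s.max() <= 1.0

    def test_permuted_rows_permute_scores_identically(self, toy_xy):
        X, y = toy_xy
        model = fit_classifier(default_spec("lasso"), {"C": 1.0}, X, y)
        perm = np.random.default_rng(0).permutation(len(X))
        s = predict_scores(model, X)
        s_perm = predict_scores(model, X.iloc[perm])
        assert np.allclose(s[perm], s_perm)

    def test_column_mismatch_rejected_with_names(self, toy_xy):
        X, y = toy_xy
        model = fit_classifier(default_spec("lasso"), {"C": 1.0}, X, y)
        with pytest.raises(ValueError, match="x2"):
            predict_scores(model, X[["x1"]])

    def test_coefficients_unavailable_for_trees(self, toy_xy):
        X, y = toy_xy
        model = fit_classifier(default_spec("cart"), {}, X, y)
        with pytest.raises(ValueError, match="importances"):
            model.coefficients


class TestGridSearch:
    def test_single_grid_point_is_best(self, toy_xy):
        X, y = toy_xy
        spec = ClassifierSpec("lasso", grid={"C": (1.0,)})
        folds = stratified_folds(y, 5, seed=0)
        cv = grid_search(X, y, spec, folds)
        assert cv.best_params == {"C": 1.0}
        assert cv.mean_auc == pytest.approx(np.mean(cv.fold_aucs))
        assert cv.sd_auc == pytest.approx(np.std(cv.fold_aucs, ddof=1))

    def test_dominant_grid_point_selected(self, toy_xy):
        # near-zero C cannot use the separating feature; moderate C can
        X, y = toy_xy
        spec = ClassifierSpec("lasso", grid={"C": (1e-6, 1.0)})
        folds = stratified_folds(y, 5, seed=0)
        cv = grid_search(X, y, spec, folds)
        assert cv.best_params == {"C": 1.0}

    def test_rerun_is_identical(self, toy_xy):
        X, y = toy_xy
        spec = ClassifierSpec("lasso", grid={"C": (0.1, 1.0)})
        folds = stratified_folds(y, 5, seed=0)
        a = grid_search(X, y, spec, folds, seed=1)
        b = grid_search(X, y, spec, folds, seed=1)
        assert a.best_params == b.best_params
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        assert np.array_equal(a.oof_scores, b.oof_scores)

    def test_fold_coefficients_collected_for_linear_methods(self, toy_xy):
        X, y = toy_xy
        spec = ClassifierSpec("lasso", grid={"C": (1.0,)})
        folds = stratified_folds(y, 5, seed=0)
        cv = grid_search(X, y, spec, folds)
        assert cv.fold_coefs.shape == (2, 5)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ClassifierSpec("boosted_ferns")

    def test_empty_grid_dimension_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            ClassifierSpec("lasso", grid={"C": ()})
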