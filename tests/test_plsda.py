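"""PLSDA core: coding, SIMPLS fit, decision rule, MCCV and metrics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirauth import (
    ClassCodeBook,
    PLSDAClassifier,
    assign_classes,
    encode_labels,
    evaluate,
    mccv_select_lv,
)
from nirauth.plsda import RankDeficiencyError, _stratified_split


def random_problem(n=30, p=8, seed=0, pos_rate=0.55):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.where(rng.random(n) < pos_rate, "POS", "NEG").astype(object)
    return X, y


class TestCoding:
    def test_encode_rule(self):
        Y = encode_labels(np.array(["POS", "NEG", "POS"], dtype=object))
        np.testing.assert_array_equal(Y, [[1, -1], [-1, 1], [1, -1]])

    def test_rows_sum_to_zero_and_round_trip(self):
        labels = np.array(["POS", "NEG", "NEG", "POS"], dtype=object)
        Y = encode_labels(labels)
        assert (Y.sum(axis=1) == 0).all()
        np.testing.assert_array_equal(ClassCodeBook().decode(Y), labels)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            encode_labels(np.array(["POS", "MAYBE"], dtype=object))


class TestAssignClasses:
    def test_zero_goes_negative(self):
        resp = np.array([[0.3, -0.3], [-0.2, 0.2], [0.0, 0.0]])
        np.testing.assert_array_equal(assign_classes(resp), ["POS", "NEG", "NEG"])

    def test_only_first_column_matters(self):
        rng = np.random.default_rng(0)
        resp = rng.standard_normal((50, 2))
        scrambled = resp.copy()
        scrambled[:, 1] = rng.standard_normal(50)
        np.testing.assert_array_equal(assign_classes(resp), assign_classes(scrambled))


class TestFit:
    def test_matches_sklearn_nipals(self):
        X, y = random_problem()
        Y = encode_labels(y)
        for a in (1, 2, 3, 6):
            ours = PLSDAClassifier(n_components=a).fit(X, y)
            ref = PLSRegression(n_components=a, scale=False).fit(X, Y)
            np.testing.assert_allclose(ours.coef_, ref.coef_.T, atol=1e-6)

    def test_max_rank_equals_least_squares(self):
        X, y = random_problem(n=25, p=6, seed=1)
        Y = encode_labels(y)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        model = PLSDAClassifier(n_components=rank).fit(X, y)
        design = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        np.testing.assert_allclose(model.predict_responses(X), design @ beta, atol=1e-8)

    def test_single_lv_on_univariate_x_is_simple_regression(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 1))
        y = np.where(rng.random(20) < 0.5, "POS", "NEG").astype(object)
        Y = encode_labels(y)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        x0 = X[:, 0] - X[:, 0].mean()
        slope = (x0 * (Y[:, 0] - Y[:, 0].mean())).sum() / (x0**2).sum()
        np.testing.assert_allclose(
            model.predict_responses(X)[:, 0], Y[:, 0].mean() + slope * x0, atol=1e-10
        )

    def test_sample_permutation_symmetry(self):
        X, y = random_problem(seed=2)
        perm = np.random.default_rng(3).permutation(len(X))
        a = PLSDAClassifier(n_components=3).fit(X, y)
        b = PLSDAClassifier(n_components=3).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-10)
        np.testing.assert_allclose(a.x_scores_[perm], b.x_scores_, atol=1e-10)

    def test_training_predictions_reproduce_fitted_responses(self):
        X, y = random_problem(seed=4)
        model = PLSDAClassifier(n_components=4).fit(X, y)
        fitted = model.x_scores_ @ model.y_loadings_.T + model.y_mean_
        np.testing.assert_allclose(model.predict_responses(X), fitted, atol=1e-8)

    def test_rank_deficiency_reports_achieved_count(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((20, 2))
        X = base @ rng.standard_normal((2, 10))  # rank 2
        y = np.where(X[:, 0] > 0, "POS", "NEG").astype(object)
        with pytest.raises(RankDeficiencyError) as err:
            PLSDAClassifier(n_components=8).fit(X, y)
        assert err.value.achieved <= 2

    @pytest.mark.parametrize("n_components", [0, 40])
    def test_component_count_validated(self, n_components):
        X, y = random_problem(n=12, p=5)
        with pytest.raises(ValueError, match="n_components"):
            PLSDAClassifier(n_components=n_components).fit(X, y)


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        X, y = random_problem(seed=7)
        model = PLSDAClassifier(n_components=3).fit(X, y)
        np.testing.assert_allclose(
            model.predict_responses(X.mean(axis=0)[None, :])[0], model.y_mean_, atol=1e-10
        )

    def test_affine_linearity(self):
        X, y = random_problem(seed=8)
        model = PLSDAClassifier(n_components=3).fit(X, y)
        x1, x2 = X[0:1], X[1:2]
        for alpha in (0.0, 0.25, 0.9):
            lhs = model.predict_responses(alpha * x1 + (1 - alpha) * x2)
            rhs = (alpha * model.predict_responses(x1)
                   + (1 - alpha) * model.predict_responses(x2))
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        X, y = random_problem()
        model = PLSDAClassifier(n_components=2).fit(X, y)
        with pytest.raises(ValueError, match="wavelength points"):
            model.predict_responses(X[:, :-1])


class TestMCCV:
    def test_separated_clusters_reach_zero_error_with_one_lv(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.05, (20, 5)), rng.normal(5, 0.05, (20, 5))])
        y = np.array(["POS"] * 20 + ["NEG"] * 20, dtype=object)
        res = mccv_select_lv(X, y, max_lv=4, T=10, fraction=0.5, seed=1)
        assert res.chosen_lv == 1
        assert res.mr_by_lv[0] == 0.0

    def test_no_signal_hovers_near_chance(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 12))
        y = np.array(["POS", "NEG"] * 30, dtype=object)  # labels independent of X
        res = mccv_select_lv(X, y, max_lv=5, T=20, fraction=0.5, seed=2)
        assert res.mr_by_lv.min() > 30.0

    def test_single_split_matches_independent_refit(self):
        # reproduce the documented split procedure, refit each candidate
        # with sklearn's NIPALS PLS and recount misclassifications
        X, y = random_problem(n=16, p=4, seed=11)
        T, fraction, seed, max_lv = 1, 0.5, 13, 3
        res = mccv_select_lv(X, y, max_lv=max_lv, T=T, fraction=fraction, seed=seed)
        tr, pr = _stratified_split(y, fraction, np.random.default_rng(seed))
        Y = encode_labels(y)
        for a in range(1, max_lv + 1):
            ref = PLSRegression(n_components=a, scale=False).fit(X[tr], Y[tr])
            pred = np.where(ref.predict(X[pr])[:, 0] > 0, "POS", "NEG")
            expected = np.mean(pred != y[pr]) * 100.0
            assert res.mr_by_lv[a - 1] == pytest.approx(expected, abs=1e-9)

    def test_deterministic_and_label_swap_invariant(self):
        X, y = random_problem(n=40, p=6, seed=12)
        kw = dict(max_lv=4, T=8, fraction=0.5, seed=3)
        a = mccv_select_lv(X, y, **kw)
        b = mccv_select_lv(X, y, **kw)
        np.testing.assert_array_equal(a.mr_by_lv, b.mr_by_lv)
        swapped = np.where(y == "POS", "NEG", "POS").astype(object)
        c = mccv_select_lv(X, swapped, **kw)
        np.testing.assert_allclose(a.mr_by_lv, c.mr_by_lv, atol=1e-12)

    def test_infeasible_max_lv_rejected(self):
        X, y = random_problem(n=10, p=50, seed=13)
        with pytest.raises(ValueError, match="max_lv"):
            mccv_select_lv(X, y, max_lv=30, T=2, fraction=0.5, seed=0)


class TestEvaluate:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,sens,spec",
        [
            (122, 9, 35, 0, 0.931, 1.000),
            (117, 14, 31, 4, 0.893, 0.886),
            (119, 12, 34, 1, 0.908, 0.971),
        ],
    )
    def test_printed_confusion_arithmetic(self, tp, fn, tn, fp, sens, spec):
        true = np.array(["POS"] * (tp + fn) + ["NEG"] * (tn + fp), dtype=object)
        pred = np.array(["POS"] * tp + ["NEG"] * fn
                        + ["NEG"] * tn + ["POS"] * fp, dtype=object)
        counts, s, q = evaluate(true, pred)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (tp, fn, tn, fp)
        assert round(s, 3) == sens
        assert round(q, 3) == spec

    def test_perfect_prediction(self):
        y = np.array(["POS", "NEG", "POS"], dtype=object)
        _, sens, spec = evaluate(y, y.copy())
        assert (sens, spec) == (1.0, 1.0)

    def test_single_class_rejected(self):
        y = np.array(["POS", "POS"], dtype=object)
        with pytest.raises(ValueError, match="specificity undefined"):
            evaluate(y, y.copy())
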