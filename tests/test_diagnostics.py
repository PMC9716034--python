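"""Split arithmetic, LASSO behavior, importances and the AUC oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import make_study
from idegnet.diagnostics import (LassoModel, evaluate_models, fit_boost,
                                 fit_lasso, fit_rf, fit_svm, roc_auc,
                                 split_7_3)


def _labeled_study(rng, n_genes=5, n_case=20, n_control=20, signal=None):
    vals = rng.standard_normal((n_genes, n_case + n_control))
    if signal is not None:
        vals[0, :n_case] += signal
    groups = ["case"] * n_case + ["control"] * n_control
    return make_study(vals, groups)


class TestSplit:
    def test_ten_samples_give_7_3(self, rng):
        st = _labeled_study(rng, n_case=5, n_control=5)
        sp = split_7_3(st, seed=1)
        assert len(sp.train) == 7 and len(sp.test) == 3

    def test_same_seed_same_split(self, rng):
        st = _labeled_study(rng)
        assert split_7_3(st, seed=4).train == split_7_3(st, seed=4).train

    def test_stratified_20_20(self, rng):
        st = _labeled_study(rng, n_case=20, n_control=20)
        sp = split_7_3(st, seed=2)
        groups = st.groups
        tr = groups.loc[sp.train]
        te = groups.loc[sp.test]
        assert (tr == "case").sum() == 14 and (tr == "control").sum() == 14
        assert (te == "case").sum() == 6 and (te == "control").sum() == 6
        assert set(sp.train) | set(sp.test) == set(st.samples)
        assert not set(sp.train) & set(sp.test)


class TestLasso:
    def test_huge_lambda_zeroes_all_coefficients(self, rng):
        from idegnet.diagnostics import _fit_l1_at
        st = _labeled_study(rng, signal=2.0)
        x = st.expr.to_numpy().T
        x = (x - x.mean(0)) / x.std(0)
        y = st.case_mask().astype(int)
        coef, _ = _fit_l1_at(x, y, lam=50.0)
        assert np.allclose(coef, 0.0)

    def test_informative_feature_gets_largest_coefficient(self, rng):
        st = _labeled_study(rng, n_case=100, n_control=100, signal=3.0)
        sp = split_7_3(st, seed=0)
        model = fit_lasso(st, list(st.genes), sp.train, seed=0)
        assert np.argmax(np.abs(model.coef)) == 0

    def test_lambda_zero_matches_unpenalized_oracle(self, rng):
        from idegnet.diagnostics import _fit_l1_at
        from sklearn.linear_model import LogisticRegression
        st = _labeled_study(rng, n_genes=2, n_case=30, n_control=30,
                            signal=1.0)
        x = st.expr.to_numpy().T
        y = st.case_mask().astype(int)
        coef, icpt = _fit_l1_at(x, y, lam=0.0)
        oracle = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10)
        oracle.fit(x, y)
        np.testing.assert_allclose(coef, oracle.coef_.ravel(), atol=1e-4)

    def test_cv_curve_shape(self, rng):
        st = _labeled_study(rng, signal=2.0)
        sp = split_7_3(st, seed=0)
        model = fit_lasso(st, list(st.genes), sp.train, seed=0, n_lambda=30)
        assert len(model.lambda_grid) == 30
        assert model.lambda_grid[0] > model.lambda_grid[-1]
        assert model.lam in model.lambda_grid
        assert model.cv_deviance.shape == (30,)

    def test_single_class_training_raises(self, rng):
        st = _labeled_study(rng, n_case=10, n_control=10)
        cases = [s for s in st.samples if st.groups[s] == "case"]
        with pytest.raises(ValueError):
            fit_lasso(st, list(st.genes), cases, seed=0)


class TestLassoScore:
    def test_unit_expression_arithmetic_five_features(self):
        model = LassoModel(
            features=["CCL3", "IFNAR1", "PIK3CG", "PTGER2", "TNF"],
            coef=np.array([1.92, 2.42, 1.25, 0.2, -4.84]),
            intercept=0.7, lam=0.1,
            lambda_grid=np.array([0.1]), cv_deviance=np.array([1.0]),
        )
        expr = {g: 1.0 for g in model.features}
        assert model.score(expr) == pytest.approx(0.95)
        assert model.score(expr, include_intercept=True) == pytest.approx(1.65)

    def test_unit_expression_arithmetic_four_features(self):
        model = LassoModel(
            features=["IFNAR1", "PIK3CG", "PTGER2", "TNF"],
            coef=np.array([0.52, 1.93, -0.65, -2.31]),
            intercept=0.0, lam=0.1,
            lambda_grid=np.array([0.1]), cv_deviance=np.array([1.0]),
        )
        assert model.score({g: 1.0 for g in model.features}) == \
            pytest.approx(-0.51)

    def test_zero_expression_gives_zero(self):
        model = LassoModel(["A", "B"], np.array([1.5, -2.0]), 3.0, 0.1,
                           np.array([0.1]), np.array([1.0]))
        assert model.score({"A": 0.0, "B": 0.0}) == 0.0

    def test_missing_feature_raises_by_name(self):
        model = LassoModel(["A", "B"], np.array([1.0, 1.0]), 0.0, 0.1,
                           np.array([0.1]), np.array([1.0]))
        with pytest.raises(KeyError, match="B"):
            model.score({"A": 1.0})


class TestTreeFamilies:
    def test_deterministic_feature_ranks_first_in_rf(self, rng):
        st = _labeled_study(rng, n_case=40, n_control=40)
        vals = st.values()
        vals[0] = np.where(st.case_mask(), 2.0, -2.0)
        st = make_study(vals, list(st.groups))
        sp = split_7_3(st, seed=1)
        ev = fit_rf(st, list(st.genes), sp.train, sp.test, trees=200, seed=1)
        assert max(ev.importance, key=ev.importance.get) == "g1"
        assert max(ev.importance_alt, key=ev.importance_alt.get) == "g1"
        assert ev.auc == 1.0

    def test_duplicated_feature_splits_importance(self, rng):
        base = _labeled_study(rng, n_genes=3, n_case=60, n_control=60,
                              signal=2.5)
        vals = base.values()
        dup = np.vstack([vals, vals[0:1]])   # g4 duplicates the signal g1
        st = make_study(dup, list(base.groups))
        sp = split_7_3(st, seed=2)
        single = fit_rf(base, list(base.genes), sp.train, sp.test, trees=300,
                        seed=2)
        split = fit_rf(st, list(st.genes), sp.train, sp.test, trees=300,
                       seed=2)
        combined = split.importance["g1"] + split.importance["g4"]
        assert combined == pytest.approx(single.importance["g1"], abs=0.25)
        assert min(split.importance["g1"], split.importance["g4"]) > 0.1
        noise = max(split.importance["g2"], split.importance["g3"])
        assert min(split.importance["g1"], split.importance["g4"]) > noise

    def test_constant_feature_zero_gain_in_boosting(self, rng):
        st = _labeled_study(rng, n_case=30, n_control=30, signal=2.0)
        vals = st.values()
        vals[1] = 5.0
        st = make_study(vals, list(st.groups))
        sp = split_7_3(st, seed=0)
        ev = fit_boost(st, list(st.genes), sp.train, sp.test, seed=0)
        assert ev.importance["g2"] == 0.0
        assert max(ev.importance, key=ev.importance.get) == "g1"

    def test_boost_deterministic_under_seed(self, rng):
        st = _labeled_study(rng, signal=1.0)
        sp = split_7_3(st, seed=3)
        e1 = fit_boost(st, list(st.genes), sp.train, sp.test, seed=3)
        e2 = fit_boost(st, list(st.genes), sp.train, sp.test, seed=3)
        assert e1.auc == e2.auc
        assert e1.importance == e2.importance

    def test_svm_separable_blobs_reach_auc_one(self, rng):
        vals = rng.standard_normal((2, 60)) * 0.3
        vals[:, :30] += 4.0
        st = make_study(vals, ["case"] * 30 + ["control"] * 30)
        sp = split_7_3(st, seed=1)
        ev = fit_svm(st, list(st.genes), sp.train, sp.test, seed=1)
        assert ev.auc == 1.0

    def test_rf_label_independence_gives_modest_importance(self, rng):
        st = _labeled_study(rng, n_case=30, n_control=30)
        sp = split_7_3(st, seed=5)
        ev = fit_rf(st, list(st.genes), sp.train, sp.test, trees=200, seed=5)
        # permutation importance of pure-noise features stays near zero
        assert max(ev.importance_alt.values()) < 0.25


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_three_quarters(self):
        assert roc_auc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_negated_scores_flip_auc(self, rng):
        scores = rng.standard_normal(20)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        assert roc_auc(-scores, labels) == pytest.approx(
            1 - roc_auc(scores, labels)
        )

    def test_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.standard_normal(n), 1)  # force some ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            cases = scores[labels == 1]
            controls = scores[labels == 0]
            wins = sum((c > d) + 0.5 * (c == d)
                       for c in cases for d in controls)
            oracle = wins / (len(cases) * len(controls))
            assert roc_auc(scores, labels) == pytest.approx(oracle)

    @given(hst.lists(hst.floats(-100, 100), min_size=4, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, xs):
        scores = np.asarray(xs)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a1 = roc_auc(scores, labels)
        # x -> 4x is exactly representable, so ties are preserved exactly
        a2 = roc_auc(scores * 4.0, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def test_all_families_share_one_split(rng):
    st = _labeled_study(rng, n_case=25, n_control=25, signal=3.0)
    evals = evaluate_models(st, list(st.genes), seed=7)
    assert set(evals) == {"LASSO", "RF", "XGBoost", "SVM"}
    for ev in evals.values():
        assert 0.0 <= ev.auc <= 1.0
    assert evals["LASSO"].auc >= 0.9
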