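"""Logistic fitting, classification metrics and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radioga as rg
from radioga.model_eval import LogisticRegressionModel
from radioga.tables import FeatureTable


def grid_mle_1feature(x, y, coarse=(-8, 8, 0.02), fine_half=0.04, fine_step=5e-4):
    """Independent oracle: dense 2D grid search of the Bernoulli
    log-likelihood for an intercept + one-slope model."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def best_on(grid0, grid1):
        t0, t1 = np.meshgrid(grid0, grid1, indexing="ij")
        eta = t0[..., None] + t1[..., None] * x
        ll = (y * eta - np.logaddexp(0, eta)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        return grid0[i], grid1[j]

    lo, hi, step = coarse
    g = np.arange(lo, hi + step, step)
    b0, b1 = best_on(g, g)
    f0 = np.arange(b0 - fine_half, b0 + fine_half, fine_step)
    f1 = np.arange(b1 - fine_half, b1 + fine_half, fine_step)
    return best_on(f0, f1)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([1] * 10 + [0] * 10)
        res = rg.fit_logistic(np.zeros((20, 0)), y)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)
        assert res.predict_prob(np.zeros((1, 0)))[0] == pytest.approx(0.5)

    def test_intercept_only_closed_form(self):
        y = np.array([1] * 15 + [0] * 5)
        res = rg.fit_logistic(np.zeros((20, 0)), y)
        assert res.intercept == pytest.approx(np.log(3), abs=1e-8)

    def test_matches_grid_search_oracle(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        res = rg.fit_logistic(x.reshape(-1, 1), y)
        b0, b1 = grid_mle_1feature(x, y)
        assert res.params[0] == pytest.approx(b0, abs=1e-3)
        assert res.params[1] == pytest.approx(b1, abs=1e-3)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(50, 3))
        y = (X[:, 0] - X[:, 2] + rng.normal(size=50) > 0).astype(int)
        res = rg.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params, ref.params, atol=1e-6)
        assert res.llf == pytest.approx(ref.llf)
        assert res.aic == pytest.approx(ref.aic)
        np.testing.assert_allclose(res.bse, ref.bse, rtol=1e-4)

    def test_perfect_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 1])
        res = rg.fit_logistic(x.reshape(-1, 1), y)
        assert not res.converged

    def test_nonfinite_rejected(self):
        with pytest.raises(rg.ValidationError):
            LogisticRegressionModel(np.array([[np.nan], [1.0]]), np.array([0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(rg.ValidationError):
            LogisticRegressionModel(np.ones((4, 1)), np.zeros(4))

    def test_summary_mentions_terms(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        res = LogisticRegressionModel(X, y, ["alpha", "beta"]).fit()
        s = res.summary()
        assert "alpha" in s and "beta" in s and "AIC" in s


class TestPredictClassify:
    @pytest.fixture
    def model(self):
        m = LogisticRegressionModel(
            np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([0, 1, 0, 1]), ["x1"]
        )
        res = m.fit()
        return res

    def test_all_zero_features_give_sigmoid_intercept(self, model):
        p = model.predict_prob(np.zeros((1, 1)))[0]
        assert p == pytest.approx(1 / (1 + np.exp(-model.intercept)))

    def test_zero_params_give_half(self, model):
        model.params = np.zeros_like(model.params)
        assert model.predict_prob(np.array([[7.0]]))[0] == 0.5

    def test_closed_form_sigmoid(self, model):
        model.params = np.array([0.0, 1.0])
        assert model.predict_prob(np.array([[np.log(3)]]))[0] == pytest.approx(0.75)

    def test_boundary_inclusive(self, model):
        model.params = np.zeros_like(model.params)
        assert model.classify(np.array([[0.0]]))[0] == 1  # prob exactly 0.5
        model.params = np.array([-0.05, 0.0])
        assert model.classify(np.array([[0.0]]))[0] == 0  # prob < 0.5

    def test_negating_coefficients_flips_labels(self, model):
        model.params = np.array([0.3, -1.2])
        x = np.linspace(-2, 2, 9).reshape(-1, 1)
        a = model.classify(x)
        model.params = -model.params
        b = model.classify(x)
        probs = model.predict_prob(x)
        flip = probs != 0.5
        np.testing.assert_array_equal(a[flip], 1 - b[flip])

    def test_missing_feature_raises(self, model):
        with pytest.raises(rg.ValidationError):
            model.predict_prob({"wrong_name": 1.0})

    def test_dict_input_aligned_by_name(self, model):
        model.params = np.array([0.0, 1.0])
        assert model.predict_prob({"x1": 0.0})[0] == 0.5


class TestAIC:
    def test_forced_arithmetic(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        res = rg.fit_logistic(X, y)
        res.llf = 0.0
        res.params = np.zeros(3)
        assert res.aic == 6.0

    def test_intercept_only_closed_form(self):
        y = np.array([0, 1] * 10)
        res = rg.fit_logistic(np.zeros((20, 0)), y)
        assert res.aic == pytest.approx(2 - 2 * 20 * np.log(0.5), abs=1e-6)

    def test_nested_model_likelihood_monotone(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + rng.normal(size=40) > 0).astype(int)
        small = rg.fit_logistic(X[:, :1], y)
        big = rg.fit_logistic(X, y)
        assert big.llf >= small.llf - 1e-9


class TestROCAUC:
    def test_perfect_ranking(self):
        assert rg.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert rg.roc_auc([0.5] * 6, [0, 1] * 3) == 0.5

    def test_four_point_hand_enumeration(self):
        assert rg.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(rg.ValidationError):
            rg.roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 20))
        scores = r.normal(size=n)
        labels = r.integers(0, 2, size=n)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert rg.roc_auc(scores, labels) == pytest.approx(
            1 - rg.roc_auc(-scores, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_perfect(self):
        y = np.array([0, 1, 1, 0])
        assert rg.confusion_metrics(y, y) == (1, 1, 1)

    def test_inverted(self):
        y = np.array([0, 1, 1, 0])
        assert rg.confusion_metrics(1 - y, y) == (0, 0, 0)

    def test_direct_counting(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 0, 0, 1, 1])  # TP=3 FN=1 TN=2 FP=2
        assert rg.confusion_metrics(pred, labels) == (0.75, 0.5, 0.625)


class TestKFoldCV:
    @pytest.fixture
    def cohort(self):
        return rg.make_feature_table(24, 6, 2, effect_size=3.0, seed=8)

    def test_folds_partition_samples(self, cohort):
        rep = rg.kfold_cv(cohort, ["f000", "f001"], k=3, seed=1)
        seen = sorted(i for f in rep.folds for i in f.test_indices)
        assert seen == list(range(24))

    def test_k3_on_six_samples(self):
        t = rg.make_feature_table(6, 3, 1, 2.0, seed=1)
        rep = rg.kfold_cv(t, ["f000"], k=3, seed=0)
        assert sorted(len(f.test_indices) for f in rep.folds) == [2, 2, 2]

    def test_class_smaller_than_k_raises(self):
        t = rg.make_feature_table(6, 3, 1, 2.0, seed=1)
        with pytest.raises(rg.ValidationError):
            rg.kfold_cv(t, ["f000"], k=6, seed=0)

    def test_deterministic_given_seed(self, cohort):
        a = rg.kfold_cv(cohort, ["f000", "f002"], k=3, seed=5)
        b = rg.kfold_cv(cohort, ["f000", "f002"], k=3, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_pooled_equals_mean_of_folds(self, cohort):
        rep = rg.kfold_cv(cohort, ["f000", "f001"], k=4, seed=2)
        for attr in ("auc", "sensitivity", "specificity", "accuracy"):
            vals = [getattr(f, attr) for f in rep.folds]
            assert getattr(rep, attr) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_separable_cohort_high_auc(self):
        t = rg.make_feature_table(60, 8, 2, effect_size=4.0, seed=3)
        genes = [f"f{i:03d}" for i in t.informative_indices]
        rep = rg.kfold_cv(t, genes, k=3, seed=3)
        assert rep.auc >= 0.95

    def test_selection_callable_refit_per_fold(self, cohort):
        calls = []

        def select(sub):
            calls.append(sub.n_samples)
            return ["f000"]

        rg.kfold_cv(cohort, select, k=3, seed=1)
        assert len(calls) == 4  # 3 training folds + 1 full refit
        assert sorted(set(calls)) == [16, 24]

    def test_report_summary_and_fields(self, cohort):
        rep = rg.kfold_cv(cohort, ["f000"], k=3, seed=1)
        d = rep.to_dict()
        assert set(d["pooled"]) == {"AUC", "Sensitivity", "Specificity", "Accuracy", "AIC"}
        assert "full_refit" in d and "AUC" in d["full_refit"]
        assert "cross-validation" in rep.summary()
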