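"""Regression estimators: parametric forms, stepwise MLR, GPR and SBBR."""

import numpy as np
import pandas as pd
import pytest

from wheatn.models import (
    BestIndexRegressor,
    GPRegressor,
    ParametricRegressor,
    StepwiseLinearRegressor,
    fit_parametric,
    holdout_split,
    sbbr,
    se_kernel,
    select_best_index,
)


class TestSEKernel:
    def test_zero_distance_returns_gamma(self):
        x = np.array([1.0, -2.0, 3.0])
        assert se_kernel(x, x, gamma=2.5, sigma=[1, 1, 1]) == pytest.approx(2.5)

    def test_one_length_scale_distance(self):
        assert se_kernel([0.0], [1.5], gamma=1.0, sigma=[1.5]) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b, s = rng.normal(size=3), rng.normal(size=3), rng.uniform(0.5, 2, 3)
        assert se_kernel(a, b, 1.3, s) == pytest.approx(se_kernel(b, a, 1.3, s), rel=1e-15)

    def test_infinite_length_scale_removes_feature(self):
        a, b = np.array([0.0, 0.0]), np.array([0.0, 100.0])
        assert se_kernel(a, b, 1.0, [1.0, 1e12]) == pytest.approx(1.0, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            se_kernel([0.0], [1.0, 2.0], 1.0, [1.0])
        with pytest.raises(ValueError):
            se_kernel([0.0], [1.0], -1.0, [1.0])


class TestParametricRegressor:
    def test_perfect_linear_fit(self):
        x = np.linspace(0, 10, 30)
        m = fit_parametric(x, 3 + 2 * x, "linear")
        assert m.r2_ == pytest.approx(1.0)
        assert m.rmse_ == pytest.approx(0.0, abs=1e-10)

    def test_power_recovery_from_log_space(self):
        x = np.linspace(0.5, 4, 50)
        m = fit_parametric(x, 2 * x**0.5, "power")
        assert m.coef_[0] == pytest.approx(2.0, abs=1e-6)
        assert m.coef_[1] == pytest.approx(0.5, abs=1e-6)

    def test_exponential_recovery(self):
        x = np.linspace(0, 3, 40)
        m = fit_parametric(x, 1.5 * np.exp(0.7 * x), "exponential")
        assert m.coef_[0] == pytest.approx(1.5, rel=1e-6)
        assert m.coef_[1] == pytest.approx(0.7, rel=1e-6)

    def test_poly2_exact(self):
        x = np.linspace(-2, 2, 25)
        m = fit_parametric(x, 1 - x + 0.5 * x**2, "poly2")
        assert np.allclose(m.coef_, [1, -1, 0.5], atol=1e-9)

    @pytest.mark.parametrize(
        "form,x,y",
        [
            ("power", np.array([1.0, 2.0]), np.array([-1.0, 1.0])),
            ("power", np.array([-1.0, 2.0]), np.array([1.0, 1.0])),
            ("logarithmic", np.array([0.0, 2.0]), np.array([1.0, 1.0])),
            ("exponential", np.array([1.0, 2.0]), np.array([0.0, 1.0])),
        ],
    )
    def test_domain_violations_rejected(self, form, x, y):
        with pytest.raises(ValueError):
            fit_parametric(x, y, form)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric(np.ones(3), np.ones(3), "cubic")


class TestHoldoutSplit:
    def test_stated_fraction_sizes(self):
        tr, va = holdout_split(104, seed=0)
        assert len(tr) == 73 and len(va) == 31

    def test_deterministic_and_partition(self):
        tr1, va1 = holdout_split(50, seed=9)
        tr2, va2 = holdout_split(50, seed=9)
        assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
        assert len(np.intersect1d(tr1, va1)) == 0
        assert len(np.union1d(tr1, va1)) == 50

    def test_stratified_allocation_keeps_total(self):
        stage = np.array(["Feekes5"] * 52 + ["Feekes11"] * 52)
        tr, va = holdout_split(104, seed=1, stage=stage)
        assert len(tr) == 73
        per = pd.Series(stage[tr]).value_counts()
        assert set(per) == {36, 37}

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(1)


class TestSelectBestIndex:
    def test_affine_copy_selected(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        X = pd.DataFrame({"noise": rng.normal(size=60), "copy": 2 * y + 1})
        name, model, info = select_best_index(X, y)
        assert name == "copy"
        assert info["abs_r"] == pytest.approx(1.0)

    def test_tie_broken_by_column_order(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        X = pd.DataFrame({"first": y.copy(), "second": y.copy()})
        name, _, _ = select_best_index(X, y)
        assert name == "first"

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            select_best_index(pd.DataFrame({"c": np.ones(20)}), np.arange(20.0))

    def test_best_index_regressor_in_sklearn_loop(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 3, 80)
        y = 2 * x**0.7 + 0.01 * rng.normal(size=80)
        X = pd.DataFrame({"idx": x, "junk": rng.normal(size=80)})
        m = BestIndexRegressor(seed=0).fit(X, y)
        assert m.index_ == "idx"
        pred = m.predict(X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.99


class TestStepwiseMLR:
    def test_single_relevant_feature_enters(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        m = StepwiseLinearRegressor().fit(X, 2.0 * X[:, 1])
        assert m.selected_features_ == [1]
        assert m.coef_[0] == pytest.approx(2.0, abs=1e-8)

    def test_duplicated_column_enters_once(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=60)
        X = pd.DataFrame({"a": base, "a_copy": base})
        y = 3 * base + 0.1 * rng.normal(size=60)
        m = StepwiseLinearRegressor().fit(X, y)
        assert sorted(m.selected_features_) in (["a"], ["a_copy"])

    def test_independent_target_gives_intercept_only(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        m = StepwiseLinearRegressor(alpha_enter=0.001).fit(X, y)
        assert m.selected_features_ == []
        assert np.allclose(m.predict(X), y.mean())


class TestGPRegressor:
    def test_constant_target_degenerates_gracefully(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        m = GPRegressor(n_restarts=1, random_state=0).fit(X, np.full(20, 3.7))
        assert np.allclose(m.predict(rng.normal(size=(5, 2))), 3.7, atol=1e-6)

    def test_zero_variance_feature_tolerated(self):
        rng = np.random.default_rng(7)
        X = np.c_[rng.normal(size=30), np.full(30, 2.0)]
        y = np.sin(X[:, 0])
        m = GPRegressor(n_restarts=1, random_state=0).fit(X, y)
        assert np.all(np.isfinite(m.predict(X)))

    def test_noise_feature_gets_larger_length_scale(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            x1, x2 = rng.normal(size=40), rng.normal(size=40)
            y = np.sin(x1) + 0.05 * rng.normal(size=40)
            m = GPRegressor(n_restarts=1, random_state=seed).fit(np.c_[x1, x2], y)
            hits += m.length_scales_[1] > m.length_scales_[0]
        assert hits >= 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(25, 3)), rng.normal(size=25)
        m1 = GPRegressor(n_restarts=2, random_state=1).fit(X, y)
        m2 = GPRegressor(n_restarts=2, random_state=1).fit(X, y)
        assert np.array_equal(m1.length_scales_, m2.length_scales_)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            GPRegressor().fit(np.ones((1, 2)), np.ones(1))


class TestSBBR:
    def test_single_feature_base_case(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"only": rng.normal(size=30)})
        tr = sbbr(X, np.sin(X["only"].to_numpy()), k_folds=10, seed=0, n_restarts=0)
        assert tr.subsets == [["only"]]
        assert tr.selected == ["only"]
        assert tr.removal_order == ["only"]

    def test_trace_is_permutation_with_monotone_sizes(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = np.sin(X["a"].to_numpy()) + 0.1 * rng.normal(size=40)
        tr = sbbr(X, y, k_folds=10, seed=0, n_restarts=0)
        assert sorted(tr.removal_order) == list("abcd")
        assert [len(s) for s in tr.subsets] == [4, 3, 2, 1]
        assert tr.selected_cv_rmse == min(tr.cv_rmse)
        assert tr.selected_cv_rmse <= tr.cv_rmse[0]

    def test_noise_feature_removed_before_signal_copy(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(70 + seed)
            y = rng.normal(size=40)
            X = pd.DataFrame({"signal": y.copy(), "noise": rng.normal(size=40)})
            tr = sbbr(X, y, k_folds=10, seed=seed, n_restarts=0)
            hits += tr.removal_order[0] == "noise"
        assert hits >= 4

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sbbr(pd.DataFrame({"a": np.ones(5)}), np.ones(5), k_folds=10)
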