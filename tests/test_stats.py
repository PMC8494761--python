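import numpy as np
import pandas as pd
import pytest

from pulsesharp.stats import (
    REQUIRED_COHORT_COLUMNS,
    cohort_report,
    fit_linear,
    kfold_cv,
    pearson_r,
)


def make_cohort(n=200, seed=11, beta_psi=-0.6, noise=0.3):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 84, n)
    sex = rng.integers(0, 2, n).astype(float)
    hr = rng.normal(72, 8, n)
    psi = 25 - 0.2 * (age - 20) + rng.normal(0, 2, n)
    raix = 40 - beta_psi * 0 + (-beta_psi) * (25 - psi) + 0.3 * (age - 50) + rng.normal(0, noise * 10, n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "hr": hr,
            "raix75": raix,
            "psi": psi,
            "excluded": np.zeros(n, dtype=bool),
        }
    )


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, -0.5 * x)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(size=10000)
        y = rng.normal(size=10000)
        r, p = pearson_r(x, y)
        assert abs(r) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(10), np.arange(10.0))

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 2.0]), np.array([3.0, 4.0]))

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, np.nan, 3.0]), np.array([1.0, 2.0, 3.0]))


class TestFitLinear:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 0.4 * x + rng.normal(size=300)
        fit = fit_linear(y, pd.DataFrame({"x": x}))
        r, _ = pearson_r(x, y)
        assert fit.beta["x"] == pytest.approx(r, abs=1e-12)

    def test_two_predictor_recovery(self):
        rng = np.random.default_rng(8)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 0.6 * x1 - 0.3 * x2 + rng.normal(0, np.sqrt(1 - 0.36 - 0.09), n)
        fit = fit_linear(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert fit.beta["x1"] == pytest.approx(0.6, abs=0.03)
        assert fit.beta["x2"] == pytest.approx(-0.3, abs=0.03)

    def test_noiseless_fit_r2_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        fit = fit_linear(3.0 * x - 1.0, pd.DataFrame({"x": x}))
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(x, pd.DataFrame({"a": x, "b": 2.0 * x}), standardize=False)

    def test_exact_solution_small_n(self):
        # n=4 points on an exact plane: unstandardized OLS reproduces it.
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": [0.0, 0.0, 1.0, 2.0]})
        y = 1.0 + 2.0 * X["a"] - 0.5 * X["b"]
        fit = fit_linear(y, X, standardize=False)
        assert fit.beta["a"] == pytest.approx(2.0, abs=1e-9)
        assert fit.beta["b"] == pytest.approx(-0.5, abs=1e-9)

    def test_log_age_requires_positive(self):
        with pytest.raises(ValueError):
            fit_linear(
                np.arange(5.0),
                pd.DataFrame({"age": [-1.0, 1, 2, 3, 4]}),
                log_age=True,
            )


class TestKfoldCv:
    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = 2.0 * X["x"] + 3.0
        cv = kfold_cv(y, X, k=10, seed=1)
        assert cv.r2_test == pytest.approx(1.0, abs=1e-9)
        assert cv.rmse_test <= 1e-9
        assert cv.mae_test <= 1e-9

    def test_constructed_explained_variance(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        y = np.sqrt(0.7) * x + np.sqrt(0.3) * rng.normal(size=n)
        cv = kfold_cv(y, pd.DataFrame({"x": x}), k=10, seed=2)
        assert cv.r2_test == pytest.approx(0.70, abs=0.03)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = X["x"] + rng.normal(0, 0.5, 100)
        a = kfold_cv(y, X, k=5, seed=3)
        b = kfold_cv(y, X, k=5, seed=3)
        assert a.r2_test == b.r2_test and a.fold_r2_test == b.fold_r2_test

    def test_too_small_n_raises(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            kfold_cv(np.arange(10.0), X, k=10)

    def test_pure_noise_mean_r2_near_zero(self):
        # Out-of-sample R^2 of noise is slightly negative on average; over
        # 20 seeds its mean must not exceed 0.02.
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame({"x": rng.normal(size=400)})
            y = rng.normal(size=400)
            vals.append(kfold_cv(y, X, k=10, seed=seed).r2_test)
        assert float(np.mean(vals)) <= 0.02


class TestCohortReport:
    def test_missing_columns_raise(self):
        table = make_cohort(50).drop(columns=["hr"])
        with pytest.raises(ValueError, match="hr"):
            cohort_report(table)

    def test_duplicate_ids_raise(self):
        table = make_cohort(50)
        table.loc[1, "subject_id"] = table.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="subject"):
            cohort_report(table)

    def test_sign_pattern_on_constructed_cohort(self):
        report = cohort_report(make_cohort(400, seed=21), k=10, seed=0)
        m = report["models"]
        assert m["model2_psi_vs_logage"]["beta"]["age"] < 0
        assert m["model1_raix_vs_logage"]["beta"]["age"] > 0
        assert m["model4_stiffness_full"]["beta"]["psi"] < 0

    def test_shuffled_psi_kills_model3(self):
        table = make_cohort(400, seed=22)
        rng = np.random.default_rng(0)
        table["raix75"] = rng.permutation(table["raix75"].to_numpy())
        report = cohort_report(table, k=10, seed=0)
        assert report["models"]["model3_stiffness_vs_psi"]["cv_r2_test"] < 0.05

    def test_small_cohort_reduces_k_with_warning(self):
        with pytest.warns(UserWarning, match="k reduced"):
            report = cohort_report(make_cohort(10, seed=23), k=10, seed=0)
        assert report["models"]["model1_raix_vs_logage"]["k"] == 5

    def test_exclusions_respected(self):
        table = make_cohort(100, seed=24)
        table.loc[:9, "excluded"] = True
        report = cohort_report(table, k=5, seed=0)
        assert report["n_excluded"] == 10
        assert report["models"]["model1_raix_vs_logage"]["n"] == 90
        assert report["models"]["model2_psi_vs_logage"]["n"] == 100

    def test_required_columns_constant(self):
        assert set(REQUIRED_COHORT_COLUMNS) == {
            "subject_id",
            "age",
            "sex",
            "hr",
            "raix75",
            "psi",
            "excluded",
        }
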