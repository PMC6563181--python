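"""Discriminant scoring, fitting, validation, and sex-difference tests."""
import numpy as np
import pandas as pd
import pytest

from sternomet.sex_estimation import (ClassificationReport,
                                      DiscriminantFunction, builtin_functions,
                                      classify_sex, fit_discriminant,
                                      loocv_classification, score_function,
                                      sex_difference_test, two_sample_t)


@pytest.fixture(scope="module")
def functions():
    return {f.name: f for f in builtin_functions()}


class TestBuiltinFunctions:
    def test_nine_functions(self, functions):
        assert len(functions) == 9

    def test_single_variable_b_row(self, functions):
        f = functions["b"]
        assert f.variables == ("B",)
        assert f.coefficients == (1.008,)
        assert f.constant == pytest.approx(-9.676)
        assert f.sectioning_point == pytest.approx(-0.1185)

    def test_sternal_area_row(self, functions):
        f = functions["sa"]
        assert f.coefficients == (0.069,)
        assert f.constant == pytest.approx(-4.019)
        assert f.sectioning_point == pytest.approx(-0.088)

    def test_three_variable_row(self, functions):
        f = functions["mw_b_csw1"]
        assert f.variables == ("MW", "B", "CSW1")
        assert f.coefficients == (0.965, 0.712, 1.793)
        assert f.constant == pytest.approx(-17.123)
        assert f.sectioning_point == pytest.approx(-0.183)

    def test_coefficient_counts_consistent(self, functions):
        for f in functions.values():
            assert len(f.variables) == len(f.coefficients)


class TestScoring:
    def test_three_variable_score_on_mean_measurements(self, functions):
        rec = {"MW": 5.63, "B": 9.46, "CSW1": 2.66}
        s = score_function(functions["mw_b_csw1"], rec)
        assert s == pytest.approx(-0.18515, abs=1e-4)
        assert classify_sex(functions["mw_b_csw1"], rec) == "female"

    def test_linear_form_roots_score_zero(self, functions):
        assert score_function(functions["b"], {"B": 9.676 / 1.008}) \
            == pytest.approx(0.0, abs=1e-12)
        assert score_function(functions["sa"], {"SA": 4.019 / 0.069}) \
            == pytest.approx(0.0, abs=1e-12)

    def test_missing_variable_named(self, functions):
        with pytest.raises(ValueError, match="CSW1"):
            score_function(functions["mw_b_csw1"], {"MW": 5.6, "B": 9.4})

    def test_large_b_classified_male(self, functions):
        assert score_function(functions["b"], {"B": 11.0}) \
            == pytest.approx(1.412, abs=1e-9)
        assert classify_sex(functions["b"], {"B": 11.0}) == "male"

    def test_boundary_tie_policy(self):
        f = DiscriminantFunction(name="unit", variables=("B",),
                                 coefficients=(1.0,), constant=0.0,
                                 sectioning_point=5.0)
        rec = {"B": 5.0}  # score lands exactly on the sectioning point
        assert classify_sex(f, rec) == "indeterminate"
        assert classify_sex(f, rec, tie_policy="male") == "male"
        assert classify_sex(f, rec, tie_policy="female") == "female"

    def test_b_axis_partition_single_crossing(self, functions):
        """Brute-force scan: the male/female partition of the B axis crosses
        exactly once, at (sectioning point - constant)/coefficient."""
        f = functions["b"]
        crossing = (-0.1185 + 9.676) / 1.008
        grid = np.linspace(5.0, 14.0, 2000)
        labels = [classify_sex(f, {"B": float(b)}) for b in grid]
        flips = [i for i in range(len(grid) - 1)
                 if labels[i] != labels[i + 1]]
        assert len(flips) == 1
        assert grid[flips[0]] < crossing < grid[flips[0] + 1]


def gaussian_groups(rng, n, mu_m, mu_f, sd=1.0, k=1):
    Xm = rng.normal(mu_m, sd, size=(n, k))
    Xf = rng.normal(mu_f, sd, size=(n, k))
    df = pd.DataFrame(np.vstack([Xm, Xf]), columns=[f"v{i}" for i in range(k)])
    df["sex"] = ["male"] * n + ["female"] * n
    return df


class TestFitDiscriminant:
    def test_one_dimensional_gaussians(self):
        rng = np.random.default_rng(0)
        df = gaussian_groups(rng, 10_000, 2.0, 0.0)
        f = fit_discriminant(df, ["v0"])
        assert f.coefficients[0] > 0
        males = df[df.sex == "male"]["v0"]
        females = df[df.sex == "female"]["v0"]
        mid = 0.5 * (score_function(f, {"v0": males.mean()})
                     + score_function(f, {"v0": females.mean()}))
        assert f.sectioning_point == pytest.approx(mid, abs=0.05)

    def test_identical_groups_warn(self):
        df = pd.DataFrame({"v0": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           "sex": ["male"] * 3 + ["female"] * 3})
        with pytest.warns(UserWarning, match="separable"):
            f = fit_discriminant(df, ["v0"])
        assert abs(f.coefficients[0]) < 1e-6

    def test_complete_separation_classifies_perfectly(self):
        rng = np.random.default_rng(1)
        df = gaussian_groups(rng, 50, 10.0, 0.0)
        f = fit_discriminant(df, ["v0"])
        report = loocv_classification(df.rename(columns={"v0": "B"}),
                                      function=DiscriminantFunction(
                                          name="f", variables=("B",),
                                          coefficients=(f.coefficients[0],),
                                          constant=f.constant,
                                          sectioning_point=f.sectioning_point))
        assert report.rate_overall == 100.0

    def test_parameter_recovery_direction(self):
        """Fitted coefficients align with the closed-form LDA direction and
        with an independent scikit-learn fit."""
        rng = np.random.default_rng(2)
        k, n = 5, 10_000
        rho = 0.4
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        delta = np.array([0.8, -0.3, 0.5, 0.1, 0.6])
        L = np.linalg.cholesky(cov)
        Xm = rng.standard_normal((n, k)) @ L.T + delta
        Xf = rng.standard_normal((n, k)) @ L.T
        df = pd.DataFrame(np.vstack([Xm, Xf]),
                          columns=[f"v{i}" for i in range(k)])
        df["sex"] = ["male"] * n + ["female"] * n
        f = fit_discriminant(df, [f"v{i}" for i in range(k)])
        w = np.asarray(f.coefficients)
        ideal = np.linalg.solve(cov, delta)
        cos = w @ ideal / np.linalg.norm(w) / np.linalg.norm(ideal)
        assert cos >= 0.99
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        lda = LinearDiscriminantAnalysis().fit(
            df[[f"v{i}" for i in range(k)]], (df.sex == "male").astype(int))
        sk = lda.coef_.ravel()
        cos_sk = w @ sk / np.linalg.norm(w) / np.linalg.norm(sk)
        assert cos_sk >= 0.999

    def test_one_class_absent_rejected(self):
        df = pd.DataFrame({"v0": [1.0, 2.0], "sex": ["male", "male"]})
        with pytest.raises(ValueError, match="per sex"):
            fit_discriminant(df, ["v0"])


class TestLoocv:
    def test_fixed_function_all_male_above_point(self, functions):
        df = pd.DataFrame({"B": [11.0, 12.0, 11.5],
                           "sex": ["male"] * 3})
        report = loocv_classification(df, function=functions["b"])
        assert report.rate_male == 100.0 and report.mode == "resubstitution"

    def test_separable_groups_high_loocv_rate(self):
        rng = np.random.default_rng(3)
        df = gaussian_groups(rng, 60, 8.0, 0.0)
        report = loocv_classification(df, variables=["v0"])
        assert report.mode == "leave-one-out"
        assert report.rate_overall >= 99.0

    def test_loocv_close_to_resubstitution_on_separable_data(self):
        rng = np.random.default_rng(4)
        df = gaussian_groups(rng, 80, 3.0, 0.0)
        f = fit_discriminant(df, ["v0"])
        resub = loocv_classification(df, function=f)
        loo = loocv_classification(df, variables=["v0"])
        assert loo.rate_overall >= resub.rate_overall - 5.0

    def test_single_record_per_class_rejected(self):
        df = pd.DataFrame({"v0": [1.0, 5.0], "sex": ["male", "female"]})
        with pytest.raises(ValueError):
            loocv_classification(df, variables=["v0"])

    def test_overall_must_be_weighted_mean(self):
        with pytest.raises(ValueError, match="weighted"):
            ClassificationReport(rate_male=80.0, rate_female=100.0,
                                 rate_overall=90.0, n_male=30,
                                 n_female=10, mode="resubstitution")
        ok = ClassificationReport(rate_male=80.0, rate_female=100.0,
                                  rate_overall=85.0, n_male=30,
                                  n_female=10, mode="resubstitution")
        assert ok.rate_overall == pytest.approx((30 * 80 + 10 * 100) / 40)


class TestSexDifference:
    def test_hand_computed_t(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_equal_groups_t_zero(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_location_invariance(self):
        a, b = np.array([1.0, 2.5, 3.0]), np.array([4.0, 5.5, 7.0])
        t1, _ = two_sample_t(a, b)
        t2, _ = two_sample_t(a + 100.0, b + 100.0)
        assert t1 == pytest.approx(t2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])

    def test_dimorphic_population_significant(self):
        from sternomet.phantom import PopulationSpec, sample_ground_truth
        table = sample_ground_truth(PopulationSpec(seed=0))
        t, p, nm, nf = sex_difference_test(table, "B")
        assert (nm, nf) == (73, 55)
        assert t > 0 and p < 0.001


class TestSyntheticPopulationRates:
    def test_builtin_rates_plausible_on_default_population(self, functions):
        """The default synthetic population, scored with the published
        single-variable functions, lands near the published rates."""
        from sternomet.phantom import PopulationSpec, sample_ground_truth
        from sternomet.osteometry import MeasurementRecord, compute_indices
        table = sample_ground_truth(PopulationSpec(seed=12))
        correct = 0
        for _, row in table.iterrows():
            label = classify_sex(functions["b"], row)
            correct += label == row.sex
        rate = 100.0 * correct / len(table)
        assert 70.0 <= rate <= 95.0
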