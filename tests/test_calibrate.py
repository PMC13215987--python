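import numpy as np
import pandas as pd
import pytest

from slicefat import calibrate
from slicefat.calibrate import (
    CalibrationModel,
    apply_sat_correction,
    apply_vat_correction,
    bland_altman,
    bootstrap_bca,
    cross_validate,
    fit_wls,
    inverse_frequency_weights,
    load_shipped_model,
    select_model,
    vif,
)
from slicefat.phantom import CohortSimSpec, generate_cohort


def vat_cohort(n=68, sd=0.0, seed=0, **kw):
    df = generate_cohort(CohortSimSpec(n=n, residual_sd=sd, seed=seed, **kw))
    return df.rename(columns={"area_auto_cm2": "vat_otsu_cm2",
                              "area_manual_cm2": "vat_manual_cm2"})


class TestApplyCorrections:
    @pytest.mark.parametrize(
        "area,obesity,expected",
        [(0.0, 0, 7.224), (100.0, 1, 126.007), (50.0, 0, 62.824)],
    )
    def test_vat_correction_values(self, area, obesity, expected):
        assert apply_vat_correction(area, obesity) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "area,adult,expected",
        [(0.0, 0, 0.67), (100.0, 1, 107.707), (200.0, 0, 208.07)],
    )
    def test_sat_correction_values(self, area, adult, expected):
        assert apply_sat_correction(area, adult) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            apply_vat_correction(-1.0, 0)

    def test_corrections_strictly_increasing_in_area(self):
        areas = np.linspace(0, 300, 10)
        vat = [apply_vat_correction(a, 0) for a in areas]
        sat = [apply_sat_correction(a, 1) for a in areas]
        assert np.all(np.diff(vat) > 0) and np.all(np.diff(sat) > 0)

    def test_shipped_models_match_direct_formulas(self):
        vat = load_shipped_model("vat_eq1")
        sat = load_shipped_model("sat_eq2")
        df = pd.DataFrame(
            {
                "vat_otsu_cm2": [80.0],
                "sat_otsu_cm2": [120.0],
                "obesity": [1],
                "age_category": ["adult"],
                "sex": ["female"],
            }
        )
        assert vat.predict(df)[0] == pytest.approx(apply_vat_correction(80.0, 1))
        assert sat.predict(df)[0] == pytest.approx(apply_sat_correction(120.0, 1))


class TestWeights:
    def test_two_cells(self):
        df = pd.DataFrame(
            {
                "sex": ["male"] * 10 + ["female"] * 30,
                "age_category": ["adult"] * 40,
            }
        )
        w = inverse_frequency_weights(df)
        np.testing.assert_allclose(w[:10], 0.1)
        np.testing.assert_allclose(w[10:], 1 / 30)

    def test_single_cell(self):
        df = pd.DataFrame({"sex": ["male"] * 5, "age_category": ["child"] * 5})
        np.testing.assert_allclose(inverse_frequency_weights(df), 0.2)

    def test_cell_weights_sum_to_one(self, rng):
        df = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], 50),
                "age_category": rng.choice(["child", "adult"], 50),
            }
        )
        w = pd.Series(inverse_frequency_weights(df))
        sums = w.groupby([df["sex"], df["age_category"]]).sum()
        np.testing.assert_allclose(sums, 1.0)


class TestFitWLS:
    def test_noiseless_recovery_of_generating_coefficients(self):
        df = vat_cohort(n=68, sd=0.0, seed=1)
        model = fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
        assert model.terms["intercept"] == pytest.approx(7.224, abs=1e-6)
        assert model.terms["vat_otsu_cm2"] == pytest.approx(1.112, abs=1e-6)
        assert model.terms["obesity"] == pytest.approx(7.583, abs=1e-6)
        assert model.r_squared == pytest.approx(1.0)

    def test_equal_weights_match_ols(self):
        df = vat_cohort(n=60, sd=5.0, seed=2)
        wls = fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"],
                      weighting=np.ones(60))
        import statsmodels.api as sm

        X = sm.add_constant(df[["vat_otsu_cm2", "obesity"]].to_numpy())
        ols = sm.OLS(df["vat_manual_cm2"].to_numpy(), X).fit()
        np.testing.assert_allclose(
            list(wls.terms.values()), ols.params, atol=1e-10
        )

    def test_duplicated_regressor_rejected(self):
        df = vat_cohort(n=40, sd=1.0, seed=3)
        df["dup"] = df["vat_otsu_cm2"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "dup"])

    def test_prediction_matches_linear_form(self):
        df = vat_cohort(n=50, sd=2.0, seed=4)
        model = fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
        manual = (
            model.terms["intercept"]
            + model.terms["vat_otsu_cm2"] * df["vat_otsu_cm2"]
            + model.terms["obesity"] * df["obesity"]
        )
        np.testing.assert_allclose(model.predict(df), manual)

    def test_json_roundtrip(self, tmp_path):
        df = vat_cohort(n=50, sd=2.0, seed=5)
        model = fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
        path = tmp_path / "m.json"
        model.to_json(path)
        back = CalibrationModel.from_json(path)
        assert back.terms == pytest.approx(model.terms)
        np.testing.assert_allclose(back.predict(df), model.predict(df))


class TestSelectModel:
    def test_only_true_terms_selected_in_simulation(self):
        # data generated with intercept + slope + obesity only
        hits = 0
        reps = 100
        for rep in range(reps):
            df = vat_cohort(n=2000, sd=2.0, seed=rep)
            chosen, _ = select_model(
                df,
                "vat_manual_cm2",
                "vat_otsu_cm2",
                ["obesity", "sex_male", "age_adult",
                 "sex_male:vat_otsu_cm2", "age_adult:vat_otsu_cm2"],
            )
            if set(chosen) == {"vat_otsu_cm2", "obesity"}:
                hits += 1
        assert hits >= 0.95 * reps

    def test_single_candidate_returned(self):
        df = vat_cohort(n=50, sd=1.0, seed=6)
        chosen, model = select_model(
            df, "vat_manual_cm2", "vat_otsu_cm2", ["obesity"]
        )
        assert chosen == ["vat_otsu_cm2", "obesity"]

    def test_deterministic(self):
        df = vat_cohort(n=100, sd=3.0, seed=7)
        a = select_model(df, "vat_manual_cm2", "vat_otsu_cm2",
                         ["obesity", "sex_male", "age_adult"])
        b = select_model(df, "vat_manual_cm2", "vat_otsu_cm2",
                         ["obesity", "sex_male", "age_adult"])
        assert a[0] == b[0]
        assert a[1].terms == pytest.approx(b[1].terms)


class TestVIF:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_correlated_pair_closed_form(self, rng):
        # construct exact sample correlation r = 0.8
        n = 200
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonalize
        z /= z.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * z
        df = pd.DataFrame({"x": x, "y": y})
        out = vif(df, ["x", "y"])
        assert out["x"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)

    def test_duplicated_term_is_infinite(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = vif(df, ["a", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_centering_reduces_interaction_vif(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "area": rng.uniform(20, 300, n),
                "obesity": (rng.random(n) < 0.4).astype(float),
            }
        )
        raw = vif(df, ["area", "obesity", "obesity:area"])
        centered = vif(df, ["area", "obesity", "obesity:area"],
                       center_interactions=True)
        assert centered["obesity:area"] < raw["obesity:area"]


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(10.0)
        ba = bland_altman(x, x)
        assert (ba.mean_diff, ba.loa_lower, ba.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.arange(10.0)
        ba = bland_altman(x + 3.0, x)
        assert ba.mean_diff == pytest.approx(3.0)
        assert ba.loa_lower == pytest.approx(3.0)
        assert ba.loa_upper == pytest.approx(3.0)

    def test_half_width_is_1p96_sd(self, rng):
        d = rng.normal(0, 2.0, 500)
        ba = bland_altman(d, np.zeros(500))
        assert ba.loa_upper - ba.mean_diff == pytest.approx(1.96 * d.std(ddof=1))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        data = rng.normal(size=50)
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_bca(data, lambda x: 3.14, seed=0)
        assert lo == hi

    def test_deterministic_given_seed(self, rng):
        data = rng.normal(size=80)
        a = bootstrap_bca(data, np.mean, n_resamples=500, seed=5)
        b = bootstrap_bca(data, np.mean, n_resamples=500, seed=5)
        assert a == b

    def test_interval_brackets_sample_mean(self, rng):
        data = rng.normal(1.0, 1.0, 200)
        lo, hi = bootstrap_bca(data, np.mean, n_resamples=2000, seed=1)
        assert lo < data.mean() < hi


class TestCrossValidation:
    def test_noiseless_loocv_has_zero_rmse(self):
        df = vat_cohort(n=40, sd=0.0, seed=8)
        res = cross_validate(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
        assert res.rmse_cm2 < 1e-6
        assert res.rmse_cm2 >= res.mae_cm2 * 0  # rmse >= 0 trivially
        assert res.r_squared == pytest.approx(1.0)

    def test_rmse_at_least_mae(self):
        df = vat_cohort(n=60, sd=8.0, seed=9)
        res = cross_validate(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
        assert res.rmse_cm2 >= res.mae_cm2 >= 0

    def test_repeated_kfold_deterministic(self):
        df = vat_cohort(n=60, sd=8.0, seed=10)
        kw = dict(scheme="kfold", k=10, repeats=3, seed=123)
        a = cross_validate(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"], **kw)
        b = cross_validate(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"], **kw)
        assert a == b

    def test_loocv_r2_tracks_in_sample_r2(self):
        # cohort at the published scale: n=68, residual sd ~ the VAT model's
        diffs = []
        for rep in range(100):
            df = vat_cohort(n=68, sd=11.5, seed=300 + rep)
            model = fit_wls(df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"])
            res = cross_validate(
                df, "vat_manual_cm2", ["vat_otsu_cm2", "obesity"]
            )
            diffs.append(res.r_squared - model.r_squared)
        assert abs(np.mean(diffs)) < 0.02
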