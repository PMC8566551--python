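"""MM-regression, diagnostics, cross-validation and lag prediction."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from amphiphen.robust import (RankDeficientError, compare_to_null, cooks_leverage,
                              fit_ols, fit_robust, loocv_rmse, m_scale,
                              predict_onset, vif)


def clean_data(rng, n=40, beta0=20.0, beta1=0.75, sd=0.1):
    x = rng.uniform(40, 90, n)
    y = beta0 + beta1 * x + rng.normal(0, sd, n)
    return x, y


class TestFit:
    def test_matches_least_squares_without_outliers(self):
        """On outlier-free data the MM fit coincides with the OLS oracle."""
        rng = np.random.default_rng(1)
        x, y = clean_data(rng)
        fit = fit_robust(y, pd.DataFrame({"x": x}))
        ols = np.polyfit(x, y, 1)
        assert fit.coefficients["intercept"] == pytest.approx(20.0, abs=0.05 * 20)
        assert fit.coefficients["x"] == pytest.approx(0.75, abs=0.05)
        assert fit.coefficients["x"] == pytest.approx(ols[0], abs=0.01)

    def test_single_gross_outlier_downweighted(self):
        rng = np.random.default_rng(2)
        x, y = clean_data(rng)
        clean = fit_robust(y, pd.DataFrame({"x": x}))
        y_out = y.copy()
        y_out[7] += 60.0
        fit = fit_robust(y_out, pd.DataFrame({"x": x}))
        assert fit.coefficients["x"] == pytest.approx(clean.coefficients["x"], abs=0.05)
        assert fit.robust_weights[7] < 0.1

    def test_quarter_contamination_bounded_shift(self):
        """< 25% gross outliers move the slope by < 3 clean standard errors."""
        rng = np.random.default_rng(3)
        x, y = clean_data(rng, n=40, sd=1.0)
        clean = fit_robust(y, pd.DataFrame({"x": x}))
        se = np.sqrt(clean.coef_covariance.loc["x", "x"])
        y_bad = y.copy()
        y_bad[:9] += 80.0  # 9/40 = 22.5%
        fit = fit_robust(y_bad, pd.DataFrame({"x": x}))
        assert abs(fit.coefficients["x"] - clean.coefficients["x"]) < 3 * se

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_robust([1.0, 2.0, 3.0], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficientError, match="a|b"):
            fit_robust(rng.normal(size=20), X)

    def test_response_shift_equivariance(self):
        """y + c shifts the intercept and all predictions by c; slope fixed."""
        rng = np.random.default_rng(5)
        x, y = clean_data(rng, sd=1.0)
        f0 = fit_robust(y, pd.DataFrame({"x": x}))
        f1 = fit_robust(y + 13.0, pd.DataFrame({"x": x}))
        assert f1.coefficients["x"] == pytest.approx(f0.coefficients["x"], abs=1e-6)
        assert f1.coefficients["intercept"] == pytest.approx(
            f0.coefficients["intercept"] + 13.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x, y = clean_data(rng, sd=2.0)
        a = fit_robust(y, pd.DataFrame({"x": x}), seed=11)
        b = fit_robust(y, pd.DataFrame({"x": x}), seed=11)
        assert (a.coefficients == b.coefficients).all()

    def test_m_scale_solves_rho_equation(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 2.5, 500)
        s = m_scale(r)
        from amphiphen.robust import BISQUARE_C_SCALE, _rho
        assert np.mean(_rho(r / s, BISQUARE_C_SCALE)) == pytest.approx(0.5, abs=1e-8)
        assert s == pytest.approx(2.5, rel=0.15)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_against_mass_rlm_mm_oracle(tmp_path):
    """Independent cross-check: MASS::rlm(method='MM') on the same data."""
    rng = np.random.default_rng(10)
    x = rng.uniform(40, 90, 30)
    y = 20 + 0.75 * x + rng.normal(0, 2.0, 30)
    y[3] += 40
    y[17] -= 35
    pd.DataFrame({"x": x, "y": y}).to_csv(tmp_path / "d.csv", index=False)
    script = textwrap.dedent("""
        library(MASS)
        d <- read.csv(commandArgs(TRUE)[1])
        f <- rlm(y ~ x, data = d, method = "MM")
        cat(coef(f)[1], coef(f)[2], f$s, "\\n")
    """)
    (tmp_path / "fit.R").write_text(script)
    out = subprocess.run(["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "d.csv")],
                         capture_output=True, text=True, check=True)
    b0, b1, s = map(float, out.stdout.split())
    fit = fit_robust(y, pd.DataFrame({"x": x}))
    assert fit.coefficients["intercept"] == pytest.approx(b0, abs=0.5)
    assert fit.coefficients["x"] == pytest.approx(b1, abs=0.01)
    assert fit.scale == pytest.approx(s, rel=0.15)


class TestCooks:
    def test_identical_response_all_zero(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 15)
        fit = fit_ols(np.full(15, 5.0), pd.DataFrame({"x": x}))
        d = cooks_leverage(fit)
        assert np.allclose(d["cooks_d"], 0.0)
        assert d["flag"].sum() == 0

    def test_single_outlier_exceeds_threshold(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 20)
        y = 1 + 2 * x + rng.normal(0, 0.2, 20)
        y[5] += 15
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        d = cooks_leverage(fit)
        assert d["cooks_d"].iloc[5] > 4 / 20
        assert d["flag"].iloc[5]
        assert d["flag"].sum() == int((d["cooks_d"] > 4 / 20).sum())

    def test_ols_mode_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.uniform(0, 10, 25)
        y = 1 + 2 * x + rng.normal(0, 1, 25)
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        d = cooks_leverage(fit)
        ref = sm.OLS(y, sm.add_constant(x)).fit().get_influence().cooks_distance[0]
        assert np.allclose(d["cooks_d"], ref, atol=1e-10)


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        x1 = np.tile([-1.0, 1.0], 10)
        x2 = np.repeat([-1.0, 1.0], 10)
        v = vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert np.allclose(v, 1.0)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        v = vif(pd.DataFrame({"x1": x, "x2": x}))
        assert np.isinf(v).all()

    def test_vif_increases_as_collinearity_tightens(self):
        """Closed form: VIF = 1/(1-r^2) grows as the noise shrinks."""
        rng = np.random.default_rng(14)
        x1 = rng.normal(size=200)
        vals = []
        for sd in (1.0, 0.5, 0.1):
            x2 = x1 + rng.normal(0, sd, 200)
            v = vif(pd.DataFrame({"x1": x1, "x2": x2}))
            r2 = np.corrcoef(x1, x2)[0, 1] ** 2
            assert v["x1"] == pytest.approx(1 / (1 - r2), rel=1e-6)
            vals.append(v["x1"])
        assert vals[0] < vals[1] < vals[2]


class TestLOOCV:
    def test_noiseless_linear_data_zero_rmse(self):
        x = np.arange(12.0)
        y = 3 + 2 * x
        assert loocv_rmse(y, pd.DataFrame({"x": x}), method="ols") == pytest.approx(0.0, abs=1e-9)

    def test_press_identity_in_ols_limit(self):
        """LOOCV by refitting equals the hat-matrix PRESS shortcut exactly."""
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 10, 18)
        y = 1 + 0.5 * x + rng.normal(0, 1, 18)
        f = fit_ols(y, pd.DataFrame({"x": x}))
        Xm = f.design.to_numpy()
        h = np.einsum("ij,jk,ik->i", Xm, np.linalg.inv(Xm.T @ Xm), Xm)
        press_rmse = np.sqrt(np.mean((f.residuals / (1 - h)) ** 2))
        assert loocv_rmse(y, pd.DataFrame({"x": x}), method="ols") == pytest.approx(
            press_rmse, abs=1e-10)

    def test_noise_predictor_does_not_improve_loocv(self):
        """Median over seeds: a pure-noise column never reduces LOOCV RMSE."""
        rng = np.random.default_rng(16)
        deltas = []
        for _ in range(20):
            x = rng.uniform(0, 10, 25)
            y = 1 + 0.5 * x + rng.normal(0, 1, 25)
            noise = rng.normal(size=25)
            base = loocv_rmse(y, pd.DataFrame({"x": x}), method="ols")
            extra = loocv_rmse(y, pd.DataFrame({"x": x, "z": noise}), method="ols")
            deltas.append(extra - base)
        assert np.median(deltas) >= 0


class TestNullComparison:
    def test_independent_response_no_gain(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(80, 5, 30)
        rep = compare_to_null(y, pd.DataFrame({"x": x}), method="ols")
        assert abs(rep["rmse_improvement"]) < 0.2 * rep["null"]["rmse_loocv"]

    def test_strong_signal_beats_null(self):
        rng = np.random.default_rng(18)
        x = rng.uniform(40, 90, 30)
        y = 20 + 0.75 * x + rng.normal(0, 1, 30)
        rep = compare_to_null(y, pd.DataFrame({"x": x}))
        assert rep["model"]["rmse_loocv"] < rep["null"]["rmse_loocv"]
        assert rep["null"]["adj_r2"] == 0.0  # by construction


class TestPrediction:
    def _fit(self, rng, n=30, beta0=44.0, beta1=0.6, sd=1.5):
        x = rng.uniform(45, 75, n)
        y = beta0 + beta1 * x + rng.normal(0, sd, n)
        return fit_robust(y, pd.DataFrame({"plant": x}))

    def test_identity_model_zero_lag(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(40, 90, 30)
        y = x + rng.normal(0, 1e-9, 30)
        fit = fit_robust(y, pd.DataFrame({"plant": x}))
        for doy in (50, 60, 80):
            res = predict_onset(fit, doy)
            assert res.lag_days == pytest.approx(0.0, abs=1e-6)

    def test_ci_brackets_point_lag(self):
        fit = self._fit(np.random.default_rng(20))
        res = predict_onset(fit, 60)
        assert res.ci95_low <= res.lag_days <= res.ci95_high
        wide = predict_onset(fit, 60, interval="prediction")
        assert wide.ci95_high - wide.ci95_low > res.ci95_high - res.ci95_low

    def test_lag_is_affine_in_plant_doy(self):
        """lag(d) has slope (slope_plant - 1): three lookups are collinear."""
        fit = self._fit(np.random.default_rng(21))
        lags = [predict_onset(fit, d).lag_days for d in (50, 60, 70)]
        slope = fit.coefficients["plant"] - 1
        assert lags[1] - lags[0] == pytest.approx(10 * slope, abs=1e-9)
        assert lags[2] - lags[1] == pytest.approx(10 * slope, abs=1e-9)

    def test_extrapolation_warning(self):
        fit = self._fit(np.random.default_rng(22))  # fitted range ~[45, 75]
        assert predict_onset(fit, 120).extrapolation_warning
        assert not predict_onset(fit, 70).extrapolation_warning

    def test_rounding_half_away_from_zero(self):
        from amphiphen.robust import PredictionResult
        r = PredictionResult(60, 65.5, 5.5, 2.5, 8.5).rounded()
        assert r["lag_days"] == 6 and r["ci95_low"] == 3
        r2 = PredictionResult(60, 59.5, -0.5, -2.5, 1.5).rounded()
        assert r2["lag_days"] == -1 and r2["ci95_low"] == -3
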