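"""Robust MM-regression of amphibian onset on plant onset (+ MAT).

The estimator is the classic MM chain: a high-breakdown S-estimate of the
residual scale (50% breakdown bisquare, c = 1.5476) found by subsampling
elemental p-subsets and local I-step refinement, followed by a redescending
bisquare M-step (c = 4.6851, 95% Gaussian efficiency) with the scale held
fixed.  Coefficient covariance uses the standard M-estimator sandwich with
the empirical psi moments; confidence intervals for predictions are
mean-response intervals on t quantiles with n - p degrees of freedom.

Diagnostics mirror the usual regression toolbox, computed on the robustly
weighted design: Cook's distance with the 4/n screening threshold (flagged,
never auto-dropped), variance inflation factors, leave-one-out
cross-validated RMSE, and a comparison against the intercept-only robust
null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("amphiphen")

BISQUARE_C_SCALE = 1.547645      # 50% breakdown S-scale tuning
BISQUARE_C_EFF = 4.685061        # 95% efficiency M-step tuning
SCALE_B = 0.5                    # E rho(u) under the normal at c = 1.5476
DEFAULT_SUBSAMPLES = 200
DEFAULT_SEED = 42


def _rho(u, c):
    """Bisquare rho normalised to max 1."""
    v = np.clip(np.abs(u) / c, 0, 1)
    return 1 - (1 - v ** 2) ** 3


def _psi(u, c):
    out = np.where(np.abs(u) <= c, u * (1 - (u / c) ** 2) ** 2, 0.0)
    return out


def _psi_prime(u, c):
    a = (u / c) ** 2
    return np.where(np.abs(u) <= c, (1 - a) * (1 - 5 * a), 0.0)


def _weights(u, c):
    """w(u) = psi(u)/u, continuous at 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(np.abs(u) <= c, (1 - (u / c) ** 2) ** 2, 0.0)
    return w


def m_scale(residuals, c: float = BISQUARE_C_SCALE, b: float = SCALE_B,
            tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve mean(rho(r/s)) = b for s by fixed-point iteration."""
    r = np.asarray(residuals, dtype=float)
    s = np.median(np.abs(r)) / 0.6745
    if s == 0:
        nz = np.abs(r[r != 0])
        if len(nz) == 0:
            return 0.0
        s = np.median(nz) / 0.6745
    for _ in range(max_iter):
        s_new = s * np.sqrt(np.mean(_rho(r / s, c)) / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


class RankDeficientError(ValueError):
    pass


@dataclass
class RobustFit:
    """A fitted MM regression."""

    coefficients: pd.Series          # intercept + slopes, named
    scale: float                     # robust residual scale (days)
    robust_weights: np.ndarray       # final bisquare weights in [0, 1]
    coef_covariance: pd.DataFrame
    n: int
    adj_r2: float
    residuals: np.ndarray
    design: pd.DataFrame             # with intercept column
    response: np.ndarray
    rmse_loocv: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def linear_predictor(self, x_row: np.ndarray) -> float:
        return float(np.asarray(x_row, dtype=float) @ self.coefficients.to_numpy())


def _check_design(X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = []
        for col in X.columns:
            others = X.drop(columns=[col])
            if others.shape[1] and np.linalg.matrix_rank(others.to_numpy()) == rank:
                bad.append(col)
        raise RankDeficientError(
            f"design is rank deficient; collinear column(s): {bad or list(X.columns)}")


def _as_design(X, names=None) -> pd.DataFrame:
    if X is None:
        return pd.DataFrame(index=range(0))
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and names is None:
        X = X.T
    names = names or [f"x{i+1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


def _irls(Xm, y, beta, scale, c, max_iter=100, tol=1e-10):
    for _ in range(max_iter):
        u = (y - Xm @ beta) / scale
        w = _weights(u, c)
        if w.sum() <= 0:
            break
        WX = Xm * w[:, None]
        try:
            beta_new = np.linalg.solve(Xm.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


def fit_robust(y, X=None, *, predictor_names=None, seed: int = DEFAULT_SEED,
               n_subsamples: int = DEFAULT_SUBSAMPLES) -> RobustFit:
    """MM-fit of ``y`` on predictors ``X`` (intercept added automatically).

    ``X=None`` or zero columns gives the intercept-only robust location fit
    used as the null model.  The elemental-subset search is driven by a
    dedicated RNG seeded with ``seed``, so a fit is reproducible bit-for-bit.
    """
    y = np.asarray(y, dtype=float)
    Xdf = _as_design(X, predictor_names)
    if len(Xdf) == 0 and X is not None and np.size(X) > 0:
        raise ValueError("empty design")
    if len(Xdf) == 0:
        Xdf = pd.DataFrame(index=range(len(y)))
    if len(Xdf) != len(y):
        raise ValueError("X and y length mismatch")
    design = Xdf.copy()
    design.insert(0, "intercept", 1.0)
    n, p = design.shape
    if n < p + 3:
        raise ValueError(f"insufficient data: n={n} < predictors+3={p + 2 + 1}")
    for col in design.columns[1:]:
        if np.ptp(design[col].to_numpy()) == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
    _check_design(design)
    Xm = design.to_numpy()

    rng = np.random.default_rng(seed)
    best_beta, best_scale = None, np.inf
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=p, replace=False)
        try:
            cand = np.linalg.solve(Xm[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        s = m_scale(y - Xm @ cand)
        if s < best_scale:
            best_scale, best_beta = s, cand
    if best_beta is None:  # all elemental subsets singular; LS fallback start
        best_beta = np.linalg.lstsq(Xm, y, rcond=None)[0]
        best_scale = m_scale(y - Xm @ best_beta)

    # refine the S-candidate: alternate I-steps and scale updates
    beta_s = best_beta
    scale = best_scale
    for _ in range(30):
        beta_new = _irls(Xm, y, beta_s, max(scale, 1e-12), BISQUARE_C_SCALE, max_iter=1)
        s_new = m_scale(y - Xm @ beta_new)
        if s_new > scale * (1 - 1e-12):
            break
        beta_s, scale = beta_new, s_new
    scale = max(m_scale(y - Xm @ beta_s), 0.0)

    # efficient M-step at fixed scale
    if scale <= 1e-12:
        beta = beta_s  # exact fit; weights all 1
        u = np.zeros(n)
    else:
        beta = _irls(Xm, y, beta_s, scale, BISQUARE_C_EFF)
        u = (y - Xm @ beta) / scale
    resid = y - Xm @ beta
    w = _weights(u, BISQUARE_C_EFF) if scale > 1e-12 else np.ones(n)

    # sandwich covariance with empirical psi moments
    if scale > 1e-12:
        num = np.sum(_psi(u, BISQUARE_C_EFF) ** 2) / (n - p)
        den = np.mean(_psi_prime(u, BISQUARE_C_EFF)) ** 2
        kappa = num / den if den > 0 else np.inf
        cov = scale ** 2 * kappa * np.linalg.inv(Xm.T @ Xm)
    else:
        cov = np.zeros((p, p))
    coef = pd.Series(beta, index=design.columns)
    cov_df = pd.DataFrame(cov, index=design.columns, columns=design.columns)

    if p == 1:
        adj = 0.0  # null model: zero explained variance by construction
    else:
        sw = w.sum()
        ybar = float((w * y).sum() / sw) if sw > 0 else float(y.mean())
        tss = float((w * (y - ybar) ** 2).sum())
        rss = float((w * resid ** 2).sum())
        r2 = 1 - rss / tss if tss > 0 else 0.0
        adj = 1 - (1 - r2) * (n - 1) / (n - p)
    return RobustFit(coefficients=coef, scale=float(scale), robust_weights=w,
                     coef_covariance=cov_df, n=n, adj_r2=float(adj),
                     residuals=resid, design=design, response=y,
                     extras={"seed": seed, "n_subsamples": n_subsamples})


def fit_ols(y, X=None, predictor_names=None) -> RobustFit:
    """Plain least squares in the same container (oracle/PRESS mode)."""
    y = np.asarray(y, dtype=float)
    Xdf = _as_design(X, predictor_names)
    if len(Xdf) == 0:
        Xdf = pd.DataFrame(index=range(len(y)))
    design = Xdf.copy()
    design.insert(0, "intercept", 1.0)
    _check_design(design)
    Xm = design.to_numpy()
    n, p = Xm.shape
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    s2 = resid @ resid / max(n - p, 1)
    cov = s2 * np.linalg.inv(Xm.T @ Xm)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float(resid @ resid) / tss if tss > 0 else 0.0
    adj = 0.0 if p == 1 else 1 - (1 - r2) * (n - 1) / (n - p)
    return RobustFit(coefficients=pd.Series(beta, index=design.columns),
                     scale=float(np.sqrt(s2)), robust_weights=np.ones(n),
                     coef_covariance=pd.DataFrame(cov, index=design.columns,
                                                  columns=design.columns),
                     n=n, adj_r2=float(adj), residuals=resid, design=design,
                     response=y, extras={"method": "ols"})


def cooks_leverage(fit: RobustFit) -> pd.DataFrame:
    """Cook's distance on the (robustly) weighted design, with 4/n flags.

    Flagged rows are reported for scrutiny, never dropped automatically.
    """
    Xm = fit.design.to_numpy()
    w = fit.robust_weights
    n, p = Xm.shape
    sw = np.sqrt(np.clip(w, 0, None))
    Xw = Xm * sw[:, None]
    G = Xw.T @ Xw
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    h = np.clip(np.einsum("ij,jk,ik->i", Xw, Ginv, Xw), 0, 1 - 1e-12)
    r = fit.residuals
    s2 = float((w * r ** 2).sum() / max(n - p, 1))
    tiny = (1e-10 * max(1.0, float(np.abs(fit.response).max()))) ** 2
    if s2 <= tiny:  # exact fit: no influence to measure
        d = np.zeros(n)
    else:
        d = w * r ** 2 * h / (p * s2 * (1 - h) ** 2)
    thresh = 4.0 / n
    return pd.DataFrame({"cooks_d": d, "leverage": h, "flag": d > thresh})


def vif(X, predictor_names=None) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R_j^2)."""
    Xdf = _as_design(X, predictor_names)
    if Xdf.shape[1] < 2:
        return pd.Series(1.0, index=Xdf.columns)
    out = {}
    for col in Xdf.columns:
        others = Xdf.drop(columns=[col])
        A = np.column_stack([np.ones(len(others)), others.to_numpy()])
        yj = Xdf[col].to_numpy()
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / tss if tss > 0 else 0.0
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def loocv_rmse(y, X=None, *, method: str = "mm", seed: int = DEFAULT_SEED,
               predictor_names=None) -> float:
    """Leave-one-out RMSE: refit on each n-1 subset, predict the held-out row."""
    y = np.asarray(y, dtype=float)
    Xdf = _as_design(X, predictor_names)
    if len(Xdf) == 0:
        Xdf = pd.DataFrame(index=range(len(y)))
    n = len(y)
    p = Xdf.shape[1] + 1
    if n < p + 3:
        raise ValueError("insufficient data for LOOCV")
    errs, skipped = [], 0
    for i in range(n):
        mask = np.arange(n) != i
        Xi = Xdf.iloc[mask] if Xdf.shape[1] else None
        try:
            if method == "ols":
                f = fit_ols(y[mask], Xi, predictor_names)
            else:
                f = fit_robust(y[mask], Xi, seed=seed)
        except (ValueError, np.linalg.LinAlgError) as exc:
            skipped += 1
            logger.warning("loocv fold %d skipped: %s", i, exc)
            continue
        x_row = np.concatenate([[1.0], Xdf.iloc[i].to_numpy()]) if Xdf.shape[1] else np.array([1.0])
        errs.append(y[i] - f.linear_predictor(x_row))
    if skipped:
        logger.warning("loocv: %d/%d folds skipped", skipped, n)
    return float(np.sqrt(np.mean(np.square(errs))))


def compare_to_null(y, X, *, method: str = "mm", seed: int = DEFAULT_SEED,
                    predictor_names=None) -> dict:
    """Model vs intercept-only null: LOOCV RMSE and adjusted R² for both."""
    fitter = fit_ols if method == "ols" else (lambda yy, XX=None, **kw: fit_robust(yy, XX, seed=seed))
    model = fitter(y, _as_design(X, predictor_names))
    null = fitter(y, None)
    out = {
        "model": {"rmse_loocv": loocv_rmse(y, X, method=method, seed=seed,
                                           predictor_names=predictor_names),
                  "adj_r2": model.adj_r2},
        "null": {"rmse_loocv": loocv_rmse(y, None, method=method, seed=seed),
                 "adj_r2": null.adj_r2,
                 "definition": "intercept-only robust location fit"},
    }
    out["rmse_improvement"] = out["null"]["rmse_loocv"] - out["model"]["rmse_loocv"]
    out["adj_r2_difference"] = out["model"]["adj_r2"] - out["null"]["adj_r2"]
    return out


@dataclass
class PredictionResult:
    """Forecast of migration onset from one plant phenophase date."""

    plant_doy: float
    predicted_amphibian_doy: float
    lag_days: float
    ci95_low: float
    ci95_high: float
    extrapolation_warning: bool = False

    def rounded(self) -> dict:
        """Integer view, rounding half away from zero (reals kept internally)."""
        r = lambda v: int(np.sign(v) * np.floor(np.abs(v) + 0.5))
        return {"plant_doy": r(self.plant_doy),
                "predicted_amphibian_doy": r(self.predicted_amphibian_doy),
                "lag_days": r(self.lag_days),
                "ci95_low": r(self.ci95_low), "ci95_high": r(self.ci95_high)}


def predict_onset(fit: RobustFit, plant_doy: float, mat: float | None = None,
                  interval: str = "mean") -> PredictionResult:
    """Predict migration onset and lag for a plant onset day.

    The single plant-DOY predictor is the non-MAT design column; MAT (when
    present in the fit) defaults to its sample mean.  The 95% interval is a
    confidence interval of the conditional mean (t quantile, n - p df);
    ``interval="prediction"`` adds the residual scale for a single new
    region-year.  Plant days more than 15 days outside the fitted range set
    ``extrapolation_warning``.
    """
    if not 1 <= plant_doy <= 366:
        raise ValueError("plant_doy must be in [1, 366]")
    cols = list(fit.design.columns)
    plant_cols = [c for c in cols if c not in ("intercept", "mat_covariate")]
    if len(plant_cols) != 1:
        raise ValueError("predict_onset needs exactly one plant predictor in the fit")
    x0 = np.zeros(len(cols))
    for j, c in enumerate(cols):
        if c == "intercept":
            x0[j] = 1.0
        elif c == "mat_covariate":
            x0[j] = mat if mat is not None else float(fit.design[c].mean())
        else:
            x0[j] = plant_doy
    pred = fit.linear_predictor(x0)
    var_mean = float(x0 @ fit.coef_covariance.to_numpy() @ x0)
    if interval == "prediction":
        var_mean += fit.scale ** 2
    tq = sps.t.ppf(0.975, df=max(fit.n - fit.p, 1))
    half = tq * np.sqrt(max(var_mean, 0.0))
    lag = pred - plant_doy
    col = plant_cols[0]
    lo_fit, hi_fit = fit.design[col].min(), fit.design[col].max()
    warn = bool(plant_doy < lo_fit - 15 or plant_doy > hi_fit + 15)
    if warn:
        logger.warning("predict_onset: plant_doy %.1f is > 15 days outside the "
                       "fitted range [%.0f, %.0f]", plant_doy, lo_fit, hi_fit)
    return PredictionResult(plant_doy=float(plant_doy), predicted_amphibian_doy=pred,
                            lag_days=lag, ci95_low=lag - half, ci95_high=lag + half,
                            extrapolation_warning=warn)


def model_table(amphibian_sd: pd.DataFrame, plant_sd: pd.DataFrame,
                response: str, predictors: list[str],
                include_mat: bool = True, regions=None) -> pd.DataFrame:
    """Assemble a fitting table: response onsets joined with 1-2 plant onsets.

    Columns: region, year, amphibian_doy, one column per plant predictor
    (named after it), and mat_covariate.
    """
    from .start_dates import REGION_MAT_MIDPOINT

    if not 1 <= len(predictors) <= 2:
        raise ValueError("models take one or at most two plant predictors")
    a = amphibian_sd[amphibian_sd["taxon"] == response]
    if regions is not None:
        a = a[a["region"].isin(regions)]
    out = a.rename(columns={"onset_doy": "amphibian_doy"})[["region", "year", "amphibian_doy"]]
    for plant in predictors:
        p = plant_sd[plant_sd["taxon"] == plant]
        p = p.rename(columns={"onset_doy": plant})[["region", "year", plant]]
        out = out.merge(p, on=["region", "year"])
    out["amphibian_doy"] = out["amphibian_doy"].astype(float)
    for plant in predictors:
        out[plant] = out[plant].astype(float)
    if include_mat:
        out["mat_covariate"] = out["region"].map(REGION_MAT_MIDPOINT)
    return out.sort_values(["region", "year"]).reset_index(drop=True)


def fit_model(table: pd.DataFrame, predictors: list[str], include_mat: bool = True,
              *, method: str = "mm", seed: int = DEFAULT_SEED,
              compute_loocv: bool = False) -> RobustFit:
    """Fit amphibian_doy ~ predictors (+ mat_covariate) from a model table.

    The MAT covariate is only identifiable when the table spans more than
    one region; with a single region it is constant and silently dropping
    it would hide a modelling choice, so it is dropped *with a warning*.
    """
    if include_mat and table["mat_covariate"].nunique() < 2:
        logger.warning("fit_model: mat_covariate is constant (single region); dropped")
        include_mat = False
    cols = list(predictors) + (["mat_covariate"] if include_mat else [])
    y = table["amphibian_doy"].to_numpy(dtype=float)
    X = table[cols]
    fit = fit_ols(y, X) if method == "ols" else fit_robust(y, X, seed=seed)
    if compute_loocv:
        fit.rmse_loocv = loocv_rmse(y, X, method=method, seed=seed)
    return fit
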