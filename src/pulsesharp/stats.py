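"""Correlation, standardized regression and k-fold cross-validation.

The analysis layer mirrors a four-model design: (1) augmentation index
against log-age, (2) sharpness index against log-age, (3) the stiffness
proxy against the sharpness index alone and (4) against sharpness index plus
age, sex and heart rate.  Coefficients are standardized (z-scored response
and predictors, log transform applied before standardization), so a
single-predictor β equals the Pearson correlation; model generalization is
summarized by tenfold cross-validated R², RMSE and MAE with standardization
parameters estimated on training folds only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "RegressionFit",
    "CVMetrics",
    "pearson_r",
    "fit_linear",
    "kfold_cv",
    "cohort_report",
    "REQUIRED_COHORT_COLUMNS",
]

log = logging.getLogger(__name__)

#: Columns a cohort table must carry for the standard four-model report.
REQUIRED_COHORT_COLUMNS = ("subject_id", "age", "sex", "hr", "raix75", "psi", "excluded")


@dataclass
class RegressionFit:
    """Standardized OLS fit summary."""

    beta: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    r2: float
    n: int
    standardized: bool
    log_age: bool


@dataclass
class CVMetrics:
    """Cross-validation metrics averaged over folds."""

    r2_test: float
    rmse_test: float
    mae_test: float
    r2_train: float
    rmse_train: float
    mae_train: float
    k: int
    seed: int
    fold_r2_test: list[float] = field(default_factory=list)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _prepare_design(
    predictors: pd.DataFrame, log_age: bool, standardize: bool
) -> pd.DataFrame:
    X = predictors.astype(float).copy()
    if log_age:
        if "age" not in X.columns:
            raise ValueError("log_age=True requires an 'age' column")
        if (X["age"] <= 0).any():
            raise ValueError("log transform requires strictly positive ages")
        X["age"] = np.log(X["age"])
    if standardize:
        for col in X.columns:
            sd = float(X[col].std(ddof=1))
            if sd == 0.0:
                raise ValueError(f"zero-variance predictor {col!r} cannot be standardized")
            X[col] = (X[col] - X[col].mean()) / sd
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # Name the offending columns: those whose R diagonal in a QR
        # factorization is numerically zero.
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        cols = ["<intercept>"] + list(X.columns)
        bad = [cols[i] for i in range(len(cols)) if diag[i] <= tol]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_linear(
    response: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    standardize: bool = True,
    log_age: bool = False,
) -> RegressionFit:
    """Ordinary least squares with standardized coefficients.

    With ``standardize=True`` both response and predictors are z-scored
    (after the optional log-age transform: log first, then standardize), so
    the coefficients are standardized β and, with a single predictor, β
    equals the Pearson correlation between predictor and response.
    """
    y = np.asarray(response, dtype=float)
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame(predictors)
    if len(predictors) != y.size:
        raise ValueError("response and predictors must have equal length")
    if y.size <= predictors.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if not np.all(np.isfinite(y)):
        raise ValueError("response must be finite")
    X = _prepare_design(predictors, log_age, standardize)
    if standardize:
        sd = float(np.std(y, ddof=1))
        if sd == 0.0:
            raise ValueError("zero-variance response cannot be standardized")
        y = (y - y.mean()) / sd
    _check_rank(X)
    model = sm.OLS(y, sm.add_constant(X.to_numpy()))
    res = model.fit()
    names = list(X.columns)
    beta = {nm: float(res.params[i + 1]) for i, nm in enumerate(names)}
    tv = {nm: float(res.tvalues[i + 1]) for i, nm in enumerate(names)}
    pv = {nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)}
    return RegressionFit(
        beta=beta,
        tvalues=tv,
        pvalues=pv,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        n=int(y.size),
        standardized=standardize,
        log_age=log_age,
    )


def kfold_cv(
    response: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    log_age: bool = False,
) -> CVMetrics:
    """k-fold cross-validated R², RMSE and MAE without leakage.

    Standardization parameters (and the optional log-age transform's
    standardization) are estimated on the training folds only and applied to
    the held-out fold; fold assignment is deterministic given ``seed``.
    """
    y = np.asarray(response, dtype=float)
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame(predictors)
    if k < 2:
        raise ValueError("k must be >= 2")
    if y.size < 2 * k:
        raise ValueError(f"need n >= 2k (n={y.size}, k={k})")
    X = _prepare_design(predictors, log_age, standardize=False).to_numpy()
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    r2s_te, rmse_te, mae_te = [], [], []
    r2s_tr, rmse_tr, mae_tr = [], [], []
    for tr_idx, te_idx in folds.split(X):
        scaler = StandardScaler().fit(X[tr_idx])
        y_mu, y_sd = float(y[tr_idx].mean()), float(y[tr_idx].std(ddof=0))
        if y_sd == 0.0:
            raise ValueError("zero-variance response in a training fold")
        Xtr, Xte = scaler.transform(X[tr_idx]), scaler.transform(X[te_idx])
        ytr = (y[tr_idx] - y_mu) / y_sd
        yte = (y[te_idx] - y_mu) / y_sd
        reg = LinearRegression().fit(Xtr, ytr)
        p_tr, p_te = reg.predict(Xtr), reg.predict(Xte)
        r2s_tr.append(r2_score(ytr, p_tr))
        rmse_tr.append(float(np.sqrt(mean_squared_error(ytr, p_tr))))
        mae_tr.append(mean_absolute_error(ytr, p_tr))
        r2s_te.append(r2_score(yte, p_te))
        rmse_te.append(float(np.sqrt(mean_squared_error(yte, p_te))))
        mae_te.append(mean_absolute_error(yte, p_te))
    return CVMetrics(
        r2_test=float(np.mean(r2s_te)),
        rmse_test=float(np.mean(rmse_te)),
        mae_test=float(np.mean(mae_te)),
        r2_train=float(np.mean(r2s_tr)),
        rmse_train=float(np.mean(rmse_tr)),
        mae_train=float(np.mean(mae_tr)),
        k=k,
        seed=seed,
        fold_r2_test=[float(v) for v in r2s_te],
    )


def _decade_groups(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    groups = {}
    edges = [(20, 39), (40, 49), (50, 59), (60, 84)]
    for lo, hi in edges:
        sub = table[(table["age"] >= lo) & (table["age"] <= hi)]
        if len(sub):
            groups[f"{lo}-{hi}"] = {
                "n": int(len(sub)),
                "psi_mean": float(sub["psi"].mean()),
                "raix75_mean": float(sub.loc[~sub["excluded"], "raix75"].mean())
                if (~sub["excluded"]).any()
                else float("nan"),
            }
    return groups


def cohort_report(table: pd.DataFrame, k: int = 10, seed: int = 0) -> dict:
    """The standard four-model analysis of a cohort feature table.

    Models: (1) rAIx@75 ~ log age, (2) PSI ~ log age, (3) stiffness proxy ~
    PSI, (4) stiffness proxy ~ PSI + age + sex + HR.  The stiffness proxy is
    rAIx@75, so models 1, 3 and 4 run on the subset not flagged for
    exclusion while model 2 runs on every subject (the sharpness index is
    defined for all morphologies).  Cohorts too small for the requested
    ``k`` are analysed with k reduced to n // 2 and a logged warning.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in cohort table")

    full = table.reset_index(drop=True)
    incl = full[~full["excluded"].astype(bool)].reset_index(drop=True)

    def run_model(name, data, response, cols, log_age):
        n = len(data)
        kk = k
        if n < 2 * k:
            kk = max(2, n // 2)
            log.warning("model %s: n=%d too small for k=%d; reduced to k=%d", name, n, k, kk)
            warnings.warn(f"model {name}: k reduced to {kk} (n={n})", stacklevel=3)
        fit = fit_linear(data[response], data[cols], standardize=True, log_age=log_age)
        cv = kfold_cv(data[response], data[cols], k=kk, seed=seed, log_age=log_age)
        return {
            "n": n,
            "beta": fit.beta,
            "pvalues": fit.pvalues,
            "adj_r2": fit.adj_r2,
            "cv_r2_test": cv.r2_test,
            "cv_rmse_test": cv.rmse_test,
            "cv_mae_test": cv.mae_test,
            "cv_r2_train": cv.r2_train,
            "k": cv.k,
            "log_age": log_age,
        }

    report = {
        "n_total": int(len(full)),
        "n_excluded": int(full["excluded"].astype(bool).sum()),
        "models": {
            "model1_raix_vs_logage": run_model("1", incl, "raix75", ["age"], True),
            "model2_psi_vs_logage": run_model("2", full, "psi", ["age"], True),
            "model3_stiffness_vs_psi": run_model("3", incl, "raix75", ["psi"], False),
            "model4_stiffness_full": run_model(
                "4", incl, "raix75", ["psi", "age", "sex", "hr"], False
            ),
        },
        "age_groups": _decade_groups(full),
        "seed": seed,
    }
    return report
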