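"""Model-development statistics: sample size, Pearson screening, OLS with
the full summary / ANOVA / coefficient-diagnostic report.

These are the statistics a clinical model-development study prints:
single-population sample size N = P(1-P)Z^2/d^2; Pearson screening of
candidate predictors against the outcome; a multiple linear regression
(ordinary least squares, fitted via statsmodels) reported as a model-summary
block (R, R^2, adjusted R^2, standard error of the estimate, Durbin-Watson),
an ANOVA block (regression/residual sums of squares, F, p) and a
per-coefficient block (B, SE, standardized beta, t, p, 95% CI, collinearity
tolerance and VIF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .weight_models import LinearModel

__all__ = [
    "SampleSizeSpec",
    "AnovaTable",
    "FittedModel",
    "sample_size",
    "pearson_select",
    "fit_mlr",
    "anova_from_ss",
    "collinearity_stats",
    "durbin_watson",
    "simulate_model2_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the single-population-proportion sample-size formula."""

    P: float  # expected prevalence, in [0, 1]
    Z: float = 1.96  # standard-normal quantile for the confidence level
    d: float = 0.05  # tolerated margin of error, in (0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.P <= 1.0):
            raise ValueError("P must lie in [0, 1]")
        if not (0.0 < self.d <= 1.0):
            raise ValueError("d must lie in (0, 1]")
        if not np.isfinite(self.Z):
            raise ValueError("Z must be finite")


def sample_size(spec: SampleSizeSpec) -> int:
    """N = P(1-P) Z^2 / d^2, rounded to the nearest integer."""
    n = spec.P * (1.0 - spec.P) * spec.Z**2 / spec.d**2
    return int(round(n))


def pearson_select(
    table: pd.DataFrame,
    target: str,
    threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen candidate predictors by Pearson correlation with the target.

    Returns a frame indexed by candidate with columns ``r``, ``p``,
    ``status`` and ``selected``, ranked by |r|.  A candidate is selected
    when |r| >= threshold and p <= alpha.  Constant candidates have no
    defined correlation and are reported with status ``"undefined"`` and
    excluded.  Rows with missing values are dropped per candidate pair
    (complete-case), with a logged count.
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    rows = []
    for cand in table.columns:
        if cand == target:
            continue
        pair = table[[cand, target]].dropna()
        n_dropped = len(table) - len(pair)
        if n_dropped:
            log.info("pearson_select: dropped %d incomplete cases for %s", n_dropped, cand)
        if len(pair) < 3:
            rows.append((cand, np.nan, np.nan, "insufficient", False))
            continue
        x = pair[cand].to_numpy(dtype=float)
        y = pair[target].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            rows.append((cand, np.nan, np.nan, "undefined", False))
            continue
        r, p = stats.pearsonr(x, y)
        selected = bool(abs(r) >= threshold and p <= alpha)
        rows.append((cand, float(r), float(p), "ok", selected))
    out = pd.DataFrame(rows, columns=["candidate", "r", "p", "status", "selected"])
    out = out.set_index("candidate")
    order = out["r"].abs().sort_values(ascending=False, na_position="last").index
    return out.loc[order]


@dataclass(frozen=True)
class AnovaTable:
    """Regression ANOVA decomposition: SS_total = SS_regression + SS_residual."""

    ss_regression: float
    ss_residual: float
    df_regression: int
    df_residual: int
    ms_regression: float
    ms_residual: float
    F: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_regression + self.ss_residual

    @property
    def df_total(self) -> int:
        return self.df_regression + self.df_residual


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit with every reported table block.

    ``coef_table`` is indexed by 'const' plus the predictor names, with
    columns B, SE, beta (standardized), t, p, ci_low, ci_high, tolerance,
    VIF (diagnostics are NaN for the constant).  ``summary`` holds R,
    r_square, adjusted_r_square, std_error_estimate, durbin_watson, n.
    """

    model: LinearModel
    coef_table: pd.DataFrame
    summary: dict
    anova: AnovaTable
    residuals: np.ndarray


def anova_from_ss(
    ss_regression: float,
    df_regression: int,
    ss_residual: float,
    df_residual: int,
) -> tuple[AnovaTable, dict]:
    """Rebuild the ANOVA block and derived summary from sums of squares.

    Also returns the summary values that follow from the decomposition
    alone: R^2 = SS_reg/SS_tot, R, adjusted R^2 = 1 - (1-R^2)(n-1)/df_res
    with n = df_reg + df_res + 1, and the standard error of the estimate
    sqrt(MS_res).  Lets printed ANOVA tables be checked for internal
    consistency without the raw data.
    """
    if df_regression <= 0 or df_residual <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_regression < 0 or ss_residual < 0:
        raise ValueError("sums of squares must be non-negative")
    ms_reg = ss_regression / df_regression
    ms_res = ss_residual / df_residual
    if ms_res > 0:
        F = ms_reg / ms_res
        p = float(stats.f.sf(F, df_regression, df_residual))
    else:
        F, p = np.inf, 0.0
    if ss_regression == 0.0:
        F, p = 0.0, 1.0
    ss_tot = ss_regression + ss_residual
    r2 = ss_regression / ss_tot if ss_tot > 0 else 0.0
    n = df_regression + df_residual + 1
    summary = {
        "R": float(np.sqrt(r2)),
        "r_square": float(r2),
        "adjusted_r_square": float(1.0 - (1.0 - r2) * (n - 1) / df_residual),
        "std_error_estimate": float(np.sqrt(ms_res)),
        "p": p,
        "n": n,
    }
    table = AnovaTable(
        ss_regression=float(ss_regression),
        ss_residual=float(ss_residual),
        df_regression=int(df_regression),
        df_residual=int(df_residual),
        ms_regression=float(ms_reg),
        ms_residual=float(ms_res),
        F=float(F),
        p=float(p),
    )
    return table, summary


def collinearity_stats(X: pd.DataFrame) -> pd.DataFrame:
    """Tolerance and VIF per predictor.

    tolerance_j = 1 - R^2 of predictor j regressed (with intercept) on the
    others; VIF_j = 1/tolerance_j.  An (almost) exactly collinear predictor
    is reported with infinite VIF and flag ``"perfectly_collinear"`` rather
    than erroring, so degenerate designs stay inspectable.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors for collinearity diagnostics")
    out = []
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            out.append((name, np.nan, np.inf, "constant"))
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        tol = 1.0 - r2
        if tol < 1e-12:
            out.append((name, 0.0, np.inf, "perfectly_collinear"))
        else:
            out.append((name, tol, 1.0 / tol, ""))
    return pd.DataFrame(out, columns=["predictor", "tolerance", "VIF", "flag"]).set_index(
        "predictor"
    )


def durbin_watson(residuals: np.ndarray) -> float:
    """Durbin-Watson statistic: sum of squared first differences over sum of
    squares; in [0, 4], near 2 for serially independent residuals."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def simulate_model2_cohort(
    n: int = 384,
    seed: int = 0,
    residual_sd: float = 349.0,
    coefficients: "tuple[float, float, float, float, float] | None" = None,
) -> pd.DataFrame:
    """Simulate a development cohort with the image-model design.

    Gestational age is drawn from the study population's distribution
    (mean 35.26 wk, sd 3.04, truncated to the 30–42 wk inclusion window);
    AC, BPD and FL (cm) grow linearly with GA at textbook third-trimester
    rates plus individual variation, giving the moderate predictor
    collinearity real biometrics show.  The outcome is the linear weight
    model (default: the image-model coefficients, intercept first in the
    order AC, BPD, FL, GA) plus Gaussian residuals of sd ``residual_sd``
    grams (the development fit's standard error of the estimate).

    Columns: ac_cm, bpd_cm, fl_cm, ga_weeks, actual_bw_g.
    """
    from .weight_models import MODEL2_IMAGE

    if coefficients is None:
        coefficients = (
            MODEL2_IMAGE.intercept,
            *(c for _, c, _ in MODEL2_IMAGE.terms),
        )
    b0, b_ac, b_bpd, b_fl, b_ga = coefficients
    rng = np.random.default_rng(seed)
    lo, hi = (30.0 - 35.26) / 3.04, (42.0 - 35.26) / 3.04
    ga = 35.26 + 3.04 * stats.truncnorm.rvs(lo, hi, size=n, random_state=rng)
    ac = -2.0 + 1.00 * ga + rng.normal(0.0, 1.5, n)
    bpd = 2.5 + 0.18 * ga + rng.normal(0.0, 0.35, n)
    fl = 0.9 + 0.175 * ga + rng.normal(0.0, 0.30, n)
    y = b0 + b_ac * ac + b_bpd * bpd + b_fl * fl + b_ga * ga + rng.normal(0.0, residual_sd, n)
    return pd.DataFrame(
        {"ac_cm": ac, "bpd_cm": bpd, "fl_cm": fl, "ga_weeks": ga, "actual_bw_g": y}
    )


def fit_mlr(X: pd.DataFrame, y: "pd.Series | np.ndarray", name: str = "mlr") -> FittedModel:
    """Ordinary least squares of y (grams) on the predictor table, with
    intercept, producing every reported block.

    Missing values are dropped listwise (logged).  Confidence intervals use
    the t quantile at the residual degrees of freedom.  A rank-deficient
    design raises, naming the collinear predictors.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    data = pd.concat([X.astype(float), y], axis=1)
    complete = data.dropna()
    if len(complete) < len(data):
        log.info("fit_mlr: dropped %d incomplete cases", len(data) - len(complete))
    Xc = complete[X.columns]
    yc = complete["y"]
    k = Xc.shape[1]
    if len(Xc) <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={len(Xc)}, k={k})")
    if (Xc.nunique() <= 1).any():
        bad = list(Xc.columns[Xc.nunique() <= 1])
        raise ValueError(f"constant predictor(s): {bad}")
    design = sm.add_constant(Xc)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        tol_tab = collinearity_stats(Xc)
        bad = list(tol_tab.index[tol_tab["flag"] != ""])
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")

    res = sm.OLS(yc, design).fit()
    ci = res.conf_int(alpha=0.05)

    sd_y = float(yc.std(ddof=1))
    betas = {c: float(res.params[c]) * float(Xc[c].std(ddof=1)) / sd_y for c in Xc.columns}
    if k >= 2:
        coll = collinearity_stats(Xc)
        tol = coll["tolerance"]
        vif = coll["VIF"]
    else:
        tol = pd.Series(1.0, index=Xc.columns)
        vif = pd.Series(1.0, index=Xc.columns)

    idx = ["const", *Xc.columns]
    coef_table = pd.DataFrame(
        {
            "B": [float(res.params[i]) for i in idx],
            "SE": [float(res.bse[i]) for i in idx],
            "beta": [np.nan, *[betas[c] for c in Xc.columns]],
            "t": [float(res.tvalues[i]) for i in idx],
            "p": [float(res.pvalues[i]) for i in idx],
            "ci_low": [float(ci.loc[i, 0]) for i in idx],
            "ci_high": [float(ci.loc[i, 1]) for i in idx],
            "tolerance": [np.nan, *[float(tol[c]) for c in Xc.columns]],
            "VIF": [np.nan, *[float(vif[c]) for c in Xc.columns]],
        },
        index=idx,
    )

    anova, derived = anova_from_ss(
        float(res.ess), int(res.df_model), float(res.ssr), int(res.df_resid)
    )
    resid = np.asarray(res.resid, dtype=float)
    summary = {
        "R": derived["R"],
        "r_square": float(res.rsquared),
        "adjusted_r_square": float(res.rsquared_adj),
        "std_error_estimate": derived["std_error_estimate"],
        "durbin_watson": durbin_watson(resid),
        "n": int(res.nobs),
    }
    linear = LinearModel(
        name=name,
        intercept=float(res.params["const"]),
        terms=tuple((c, float(res.params[c]), "") for c in Xc.columns),
    )
    log.info(
        "fit_mlr: n=%d k=%d R2=%.4f F(%d,%d)=%.3f",
        int(res.nobs), k, summary["r_square"], anova.df_regression, anova.df_residual, anova.F,
    )
    return FittedModel(
        model=linear, coef_table=coef_table, summary=summary, anova=anova, residuals=resid
    )
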