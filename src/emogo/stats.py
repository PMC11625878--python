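"""Dimensional inference layer.

Pearson and partial (covariate-adjusted) correlations with exact-t
p-values, Bonferroni correction, hierarchical OLS regression with the
R²-change F test, variance-inflation diagnostics, and the sensitivity
(critical-r) computation.  Regression machinery is ordinary least squares
via statsmodels; standardized betas come from refitting on z-scored
variables (the convention most psychology software prints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    t: float
    p: float
    alpha: float = 0.05
    covariates: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.r <= 1.0000001:
            raise ValueError("|r| must not exceed 1")


def _finite_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite (drop missing values first)")
    return x, y


def _r_to_result(r: float, n: int, k_cov: int, alpha: float,
                 covariates: tuple[str, ...]) -> CorrelationResult:
    df = n - 2 - k_cov
    r = float(np.clip(r, -1.0, 1.0))
    if df <= 0:
        raise ValueError("not enough observations for the requested correlation")
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, n=n, df=df, t=float(t), p=float(p),
                             alpha=alpha, covariates=covariates)


def pearson(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with the exact two-tailed t test."""
    x, y = _finite_xy(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    return _r_to_result(r, n, 0, alpha, ())


def partial_correlation(x, y, covariates, names: tuple[str, ...] = (),
                        alpha: float = 0.05) -> CorrelationResult:
    """Correlation of x and y after linearly removing the covariates.

    ``covariates`` is (n, k) (or 1-D for a single covariate); df = n-2-k.
    An empty covariate set reduces to :func:`pearson`.
    """
    x, y = _finite_xy(x, y)
    z = np.asarray(covariates, dtype=float)
    if z.size == 0:
        return pearson(x, y, alpha=alpha)
    if z.ndim == 1:
        z = z[:, None]
    n, k = z.shape
    if n != len(x):
        raise ValueError("covariate rows must match x/y length")
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return _r_to_result(r, n, k, alpha, names or tuple(f"c{j}" for j in range(k)))


def bonferroni(alpha: float, m: int) -> float:
    """Corrected per-test alpha for a family of m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bonferroni_reject(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean decisions p < alpha/m for the whole family."""
    p = np.asarray(p_values, dtype=float)
    return p < bonferroni(alpha, p.size)


def critical_r(n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Smallest |r| reaching significance at alpha with df = n-2.

    r_crit = t_(1-alpha/tails, n-2) / sqrt(t^2 + n - 2).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 2
    t = sps.t.ppf(1.0 - alpha / tails, df)
    return float(t / np.sqrt(t * t + df))


def detectable_rho(n: int, alpha: float = 0.05, power: float = 0.95,
                   tails: int = 2) -> float:
    """Population correlation detectable at the given power (Fisher-z)."""
    if n < 4:
        raise ValueError("need n >= 4")
    za = sps.norm.ppf(1.0 - alpha / tails)
    zb = sps.norm.ppf(power)
    return float(np.tanh((za + zb) / np.sqrt(n - 3)))


@dataclass
class RegressionStep:
    """One step of a hierarchical regression (coefficients incl. intercept)."""

    coef: pd.DataFrame       # index: const + predictors; B, SE, beta, t, p, ci_low, ci_high
    r2: float
    f: float
    f_p: float
    df_model: int
    df_resid: int


@dataclass
class HierRegressionResult:
    steps: list[RegressionStep]
    delta_r2: float
    delta_f: float
    delta_df: tuple[int, int]
    delta_f_p: float
    vif: pd.Series           # per predictor in the full model


def vif(design: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor (intercept added internally).

    Perfectly collinear predictors yield ``inf``.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(X.columns):
            out[name] = float(variance_inflation_factor(Xc, j + 1))
    return pd.Series(out, name="vif")


def _fit_step(y: np.ndarray, X: pd.DataFrame, alpha: float) -> RegressionStep:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    zX = (X - X.mean()) / X.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX, has_constant="add")).fit()
    ci = model.conf_int(alpha=alpha)
    coef = pd.DataFrame({
        "B": model.params, "SE": model.bse,
        "beta": zfit.params.reindex(model.params.index),
        "t": model.tvalues, "p": model.pvalues,
        "ci_low": ci[0], "ci_high": ci[1],
    })
    coef.loc["const", "beta"] = np.nan
    return RegressionStep(coef=coef, r2=float(model.rsquared),
                          f=float(model.fvalue), f_p=float(model.f_pvalue),
                          df_model=int(model.df_model), df_resid=int(model.df_resid))


def hierarchical_regression(y, step1: pd.DataFrame, step2: pd.DataFrame,
                            alpha: float = 0.05) -> HierRegressionResult:
    """Two-step nested OLS with the R²-change F test.

    ΔF = (ΔR²/q) / ((1-R²_full)/(n-k_full-1)) with q = number of added
    predictors; its p-value uses the F(q, n-k_full-1) reference
    distribution.  Raises on a rank-deficient full design, reporting VIFs.
    """
    y = np.asarray(y, dtype=float)
    step1 = pd.DataFrame(step1)
    step2 = pd.DataFrame(step2)
    if set(step1.columns) & set(step2.columns):
        raise ValueError("step-2 additions duplicate step-1 predictors")
    full = pd.concat([step1, step2], axis=1)
    n = len(y)
    k_full = full.shape[1]
    if n <= k_full + 1:
        raise ValueError("need n > total predictors + 1")
    design = sm.add_constant(full.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear design; VIFs:\n{vif(full)}")

    s1 = _fit_step(y, step1, alpha)
    s2 = _fit_step(y, full, alpha)
    q = step2.shape[1]
    df_resid = n - k_full - 1
    delta_r2 = s2.r2 - s1.r2
    denom = (1.0 - s2.r2) / df_resid
    if denom <= 0:   # saturated full model: no residual variance
        delta_f = np.inf if delta_r2 > 0 else 0.0
    else:
        delta_f = (delta_r2 / q) / denom
    delta_p = float(sps.f.sf(delta_f, q, df_resid))
    return HierRegressionResult(
        steps=[s1, s2], delta_r2=float(delta_r2), delta_f=float(delta_f),
        delta_df=(q, df_resid), delta_f_p=delta_p,
        vif=vif(full) if k_full >= 2 else pd.Series(dtype=float),
    )


def correlation_table(data: pd.DataFrame, x_vars: list[str], y_vars: list[str],
                      covariates: list[str] | None = None,
                      alpha: float = 0.05,
                      bonferroni_m: int | None = None) -> pd.DataFrame:
    """Tidy r/p table over x_vars x y_vars, optionally covariate-adjusted.

    Rows with missing values in the involved columns are dropped pairwise.
    ``bonferroni_m`` (default: len(y_vars)) sets the per-family corrected
    alpha used for the significance flag.
    """
    m = bonferroni_m if bonferroni_m is not None else len(y_vars)
    a_corr = bonferroni(alpha, m)
    cov_names = tuple(covariates or ())
    rows = []
    for xv in x_vars:
        for yv in y_vars:
            cols = [xv, yv, *cov_names]
            sub = data[cols].dropna()
            res = partial_correlation(sub[xv], sub[yv],
                                      sub[list(cov_names)].to_numpy() if cov_names else np.empty((len(sub), 0)),
                                      names=cov_names, alpha=a_corr)
            rows.append(dict(x=xv, y=yv, r=res.r, n=res.n, df=res.df, t=res.t,
                             p=res.p, corrected_alpha=a_corr,
                             significant=res.significant,
                             covariates=",".join(cov_names)))
    return pd.DataFrame(rows)
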