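"""Average-treatment-effect machinery.

Propensity scores by logistic regression, inverse-probability-of-treatment
weighted Kaplan-Meier / log-rank / Cox (the adjusted hazard ratio HRa),
doubly-robust residual-on-residual estimation of the treatment odds ratio
(ORd), fixed-horizon binarization of survival outcomes, and binomial
proportion confidence intervals for reported rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .survival import kaplan_meier, log_rank

__all__ = ["PropensityResult", "fit_propensity", "iptw_km_logrank",
           "adjusted_hr", "binary_outcome_at", "drl_or", "proportion_ci",
           "naive_or", "standardized_mean_differences", "round_half_up"]


@dataclass
class PropensityResult:
    p: np.ndarray              # P(gross-total resection | x), clipped
    weights: np.ndarray        # IPTW weights (stabilized by default)
    clipped_count: int
    stabilized: bool
    coef: np.ndarray
    intercept: float


def _fit_logistic(X, y):
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
    lr.fit(X, y)
    p = lr.predict_proba(X)[:, 1]
    return lr, p


def fit_propensity(X, T, clip: tuple = (0.01, 0.99),
                   stabilized: bool = True) -> PropensityResult:
    """Logistic-regression propensity scores and IPTW weights.

    Probabilities are clipped to ``clip``; unstabilized weights are 1/p for
    the treated and 1/(1-p) for controls, stabilized weights multiply by the
    marginal arm probabilities so they average near 1.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T).astype(int)
    if T.min() == T.max():
        raise ValueError("both treatment arms must be present")
    lr, p_raw = _fit_logistic(X, T)
    if np.any(p_raw < 1e-8) or np.any(p_raw > 1 - 1e-8):
        raise ValueError("propensity model separated the arms; "
                         "consider regularization or coarser covariates")
    p = np.clip(p_raw, *clip)
    clipped = int((p != p_raw).sum())
    w = np.where(T == 1, 1.0 / p, 1.0 / (1.0 - p))
    if stabilized:
        pt = T.mean()
        w = w * np.where(T == 1, pt, 1.0 - pt)
    return PropensityResult(p, w, clipped, stabilized,
                            lr.coef_.ravel().copy(), float(lr.intercept_[0]))


def iptw_km_logrank(time, event, T, weights):
    """Weighted per-arm Kaplan-Meier curves and weighted log-rank p-value.

    Reduces to the unweighted analysis at unit weights; curves and p are
    invariant to rescaling all weights by a constant.
    """
    T = np.asarray(T).astype(int)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    km = {a: kaplan_meier(time[T == a], event[T == a], weights[T == a])
          for a in (0, 1)}
    chi2, p = log_rank(time, event, T, weights)
    return km[0], km[1], p


def adjusted_hr(time, event, T, weights, level: float = 0.95):
    """IPTW-weighted univariable Cox HR of treatment with robust variance."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({
        "treatment": np.asarray(T).astype(int),
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event).astype(int),
        "w": np.asarray(weights, dtype=float),
    })
    if df.groupby("treatment")["event"].sum().min() == 0:
        raise ValueError("events required in both arms")
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="time", event_col="event", weights_col="w",
            robust=True)
    z = norm.ppf(1 - (1 - level) / 2)
    coef = float(cph.params_["treatment"])
    se = float(cph.standard_errors_["treatment"])
    return float(np.exp(coef)), (float(np.exp(coef - z * se)),
                                 float(np.exp(coef + z * se)))


def binary_outcome_at(time, event, horizon: float):
    """Fixed-horizon binary outcome with a usability mask.

    Y = 1 if a cause-specific death occurred by the horizon; Y = 0 if the
    patient was followed event-free beyond it; patients censored event-free
    before the horizon are masked out.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    died_by = (event == 1) & (time <= horizon)
    survived_past = time > horizon
    mask = died_by | survived_past
    Y = died_by.astype(int)
    return Y, mask


def naive_or(T, Y, level: float = 0.95):
    """Unadjusted odds ratio of the outcome on treatment (logistic fit)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(T, dtype=float))
    fit = sm.GLM(np.asarray(Y, dtype=float), X,
                 family=sm.families.Binomial()).fit()
    z = norm.ppf(1 - (1 - level) / 2)
    b, se = fit.params[1], fit.bse[1]
    return float(np.exp(b)), (float(np.exp(b - z * se)), float(np.exp(b + z * se)))


def drl_or(X, T, Y, mask=None, level: float = 0.95):
    """Doubly-robust residual-on-residual treatment effect.

    Stage 1 fits logistic nuisance models for the outcome, Yhat(x), and the
    treatment, phat(x); stage 2 regresses the outcome residual Y - Yhat on
    the treatment residual T - phat (partially linear form), with a
    heteroskedasticity-robust slope CI.  Returns
    ``(or_d, (lo, hi), slope, slope_ci)`` where or_d = exp(slope); the raw
    slope (a risk-difference-scale quantity) is reported alongside because
    exponentiating it is only one reading of a "two-stage adjusted OR".
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    T = np.asarray(T).astype(float)
    Y = np.asarray(Y).astype(float)
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        X, T, Y = X[keep], T[keep], Y[keep]
    if len(np.unique(T)) < 2 or len(np.unique(Y)) < 2:
        raise ValueError("both arms and both outcome classes must be present")

    if X.shape[1] == 0:
        yhat = np.full(len(Y), Y.mean())
        phat = np.full(len(T), T.mean())
    else:
        _, yhat = _fit_logistic(X, Y.astype(int))
        _, phat = _fit_logistic(X, T.astype(int))
    ry = Y - yhat
    rt = T - phat
    if np.var(rt) < 1e-12 or np.var(ry) < 1e-16:
        raise ValueError("degenerate residuals; stage-2 regression undefined")
    ols = sm.OLS(ry, sm.add_constant(rt)).fit(cov_type="HC1")
    z = norm.ppf(1 - (1 - level) / 2)
    slope, se = ols.params[1], ols.bse[1]
    slope_ci = (float(slope - z * se), float(slope + z * se))
    return (float(np.exp(slope)),
            (float(np.exp(slope_ci[0])), float(np.exp(slope_ci[1]))),
            float(slope), slope_ci)


def round_half_up(x, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def proportion_ci(events: int, n: int, level: float = 0.95):
    """Wald binomial proportion interval, clipped to [0, 1].

    p +/- z * sqrt(p(1-p)/n).  Report percentages with
    :func:`round_half_up` to one decimal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    p = events / n
    z = norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def standardized_mean_differences(X, T, weights=None) -> np.ndarray:
    """Per-column absolute standardized mean differences between arms."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T).astype(int)
    w = np.ones(len(T)) if weights is None else np.asarray(weights, dtype=float)

    def wmean(A, ww):
        return (A * ww[:, None]).sum(0) / ww.sum()

    def wvar(A, ww):
        mu = wmean(A, ww)
        return (ww[:, None] * (A - mu) ** 2).sum(0) / ww.sum()

    m1, m0 = wmean(X[T == 1], w[T == 1]), wmean(X[T == 0], w[T == 0])
    v1, v0 = wvar(X[T == 1], w[T == 1]), wvar(X[T == 0], w[T == 0])
    pooled = np.sqrt((v1 + v0) / 2.0)
    pooled[pooled == 0] = 1.0
    return np.abs(m1 - m0) / pooled
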