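"""Diagnostic statistics: logistic modelling, ROC analysis, and
threshold-level accuracy measures.

This is the statistics chain applied to the per-quadrant feature matrix:
multiple logistic regression with backward stepwise elimination by Akaike's
information criterion (AIC), empirical ROC curves with the optimal cutpoint
chosen at the highest Youden index J = sensitivity + specificity - 1, and
threshold metrics (sensitivity, specificity, likelihood ratios, predictive
values) with exact Clopper-Pearson 95% confidence intervals, matching the
conventions of clinical diagnostic-accuracy reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .exceptions import ConvergenceError, SeparationError

__all__ = [
    "LogisticModel",
    "RocResult",
    "ThresholdMetrics",
    "PublishedThreshold",
    "PUBLISHED_THRESHOLDS",
    "clopper_pearson",
    "fit_logistic",
    "stepwise_aic",
    "roc_curve",
    "youden_threshold",
    "threshold_metrics",
]


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via the beta-quantile relation.

    Lower bound is 0 when successes = 0 and upper bound is 1 when
    successes = n (one-sided exact limits at the boundary).
    """
    if not (0 <= successes <= n) or n <= 0:
        raise ValueError("require 0 <= successes <= n with n > 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


# ---------------------------------------------------------------------------
# Logistic regression (IRLS) and backward stepwise elimination by AIC
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit.

    ``coefficients[0]`` is the intercept, followed by one coefficient per
    selected feature; standard errors come from the observed information
    at the optimum. ``separated`` marks complete separation, where the MLE
    does not exist and coefficients/SEs are the diverging iterates at the
    iteration cap.
    """

    selected_features: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    aic: float
    log_likelihood: float
    n_obs: int
    n_iter: int
    separated: bool = False

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[1 + self.selected_features.index(name)])


def _irls(
    X: np.ndarray, y: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    ll = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        # working response and weighted least squares step
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError:
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], sw * z, rcond=None)
        pc = np.clip(expit(X @ beta), 1e-300, 1 - 1e-16)
        ll = float(y @ np.log(pc) + (1 - y) @ np.log1p(-pc))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    eta = X @ beta
    margins = np.where(y == 1, eta, -eta)
    separated = bool(np.all(margins > 0) and ll > -1e-4 * max(n, 1))
    info = X.T @ (X * np.clip(expit(eta) * (1 - expit(eta)), 1e-12, None)[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    return beta, se, ll, n_iter, separated


def fit_logistic(
    features: pd.DataFrame,
    labels,
    selected: list[str] | None = None,
    allow_separation: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Fit a binary logistic regression by iteratively reweighted least
    squares on the chosen feature columns (all columns by default).

    Raises :class:`SeparationError` on complete separation unless
    *allow_separation* is set (the stepwise search sets it so AIC, which
    tends to 2k under separation, stays comparable across submodels), and
    :class:`ConvergenceError` if the log-likelihood has not stabilised
    within *max_iter* iterations.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    names = list(features.columns) if selected is None else list(selected)
    Xf = features[names].to_numpy(dtype=float) if names else np.empty((len(y), 0))
    if not np.all(np.isfinite(Xf)):
        raise ValueError("feature matrix contains non-finite values")
    X = np.column_stack([np.ones(len(y)), Xf])

    beta, se, ll, n_iter, separated = _irls(X, y, tol, max_iter)
    if separated and not allow_separation:
        raise SeparationError(
            "complete separation: the logistic MLE does not exist"
        )
    if not separated and n_iter >= max_iter:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    k = X.shape[1]
    return LogisticModel(
        selected_features=names,
        coefficients=beta,
        standard_errors=se,
        aic=2 * k - 2 * ll,
        log_likelihood=ll,
        n_obs=len(y),
        n_iter=n_iter,
        separated=separated,
    )


def stepwise_aic(
    features: pd.DataFrame,
    labels,
    allow_separation: bool = False,
    direction: str = "backward",
) -> LogisticModel:
    """Backward stepwise elimination: starting from the full model, drop at
    each step the term whose removal lowers AIC most, until no removal
    lowers it. Ties break toward the earliest feature column.
    """
    if direction != "backward":
        raise ValueError("only backward elimination is implemented")
    current = list(features.columns)
    if len(current) < 2:
        raise ValueError("stepwise elimination needs at least 2 candidate features")

    def fit(names: list[str]) -> LogisticModel:
        return fit_logistic(features, labels, selected=names, allow_separation=allow_separation)

    model = fit(current)
    while len(current) > 1:
        best_model = None
        best_aic = model.aic
        for name in current:  # column order; strict < keeps the earliest tie
            cand = [f for f in current if f != name]
            m = fit(cand)
            if m.aic < best_aic - 1e-12:
                best_aic = m.aic
                best_model = m
        if best_model is None:
            break
        model = best_model
        current = list(model.selected_features)
    return model


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC: one operating point per candidate cutpoint, with the
    convention that a case is called positive when score > threshold."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all distinct cutpoints, AUC by the trapezoid rule
    (equal to the tie-corrected Mann-Whitney statistic), SE by the
    Hanley-McNeil formula, and a normal-approximation 95% CI clipped to
    [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    thr = np.concatenate([[-np.inf], np.unique(s)])
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    sens = (n1 - np.searchsorted(pos, thr, side="right")) / n1
    spec = np.searchsorted(neg, thr, side="right") / n0

    # thr ascends, so (fpr, tpr) descends from (1, 1) to (0, 0); reverse it
    fpr = (1 - spec)[::-1]
    tpr = sens[::-1]
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(math.sqrt(max(var, 0.0)))
    z = norm.ppf(0.975)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return RocResult(
        thresholds=thr,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        auc_ci95=ci,
        scores=s,
        labels=y,
    )


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------


@dataclass
class ThresholdMetrics:
    """Confusion matrix and accuracy measures at one cutpoint.

    Rates are proportions in [0, 1] with exact (Clopper-Pearson) 95% CIs;
    likelihood-ratio CIs use the log-transform (Simel) method and are None
    when undefined (a zero cell makes the log-LR variance infinite).
    """

    cutpoint: float
    direction: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden_j: float
    lr_positive: float
    lr_positive_ci: tuple[float, float] | None
    lr_negative: float
    lr_negative_ci: tuple[float, float] | None
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]


def _lr_ci(lr: float, a: int, m: int, b: int, n: int, level: float) -> tuple[float, float] | None:
    """Simel log-method CI for a likelihood ratio built from proportions
    a/m and b/n; undefined when either cell is 0 or the LR is 0/inf."""
    if lr == 0.0 or not math.isfinite(lr) or a == 0 or b == 0:
        return None
    z = norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


def threshold_metrics(
    scores,
    labels,
    cutpoint: float,
    direction: str = "greater",
    level: float = 0.95,
) -> ThresholdMetrics:
    """Evaluate one diagnostic cutpoint.

    ``direction='greater'`` calls a case positive when score > cutpoint
    (strict); ``'less_equal'`` when score <= cutpoint. Sensitivity,
    specificity and predictive values carry exact binomial CIs; predictive
    values are computed at the sample prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if direction == "greater":
        call = s > cutpoint
    elif direction == "less_equal":
        call = s <= cutpoint
    else:
        raise ValueError("direction must be 'greater' or 'less_equal'")
    tp = int(np.sum(call & (y == 1)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    fp = int(np.sum(call & (y == 0)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = math.inf if spec == 1.0 else sens / (1 - spec)
    lr_neg = (1 - sens) / spec if spec > 0 else math.nan

    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    npv = tn / (tn + fn) if tn + fn > 0 else math.nan
    nan_ci = (math.nan, math.nan)
    return ThresholdMetrics(
        cutpoint=float(cutpoint),
        direction=direction,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(tp, tp + fn, level),
        specificity=spec,
        specificity_ci=clopper_pearson(tn, tn + fp, level),
        youden_j=sens + spec - 1,
        lr_positive=lr_pos,
        lr_positive_ci=_lr_ci(lr_pos, tp, tp + fn, fp, fp + tn, level),
        lr_negative=lr_neg,
        lr_negative_ci=_lr_ci(lr_neg, fn, tp + fn, tn, fp + tn, level),
        ppv=ppv,
        ppv_ci=clopper_pearson(tp, tp + fp, level) if tp + fp > 0 else nan_ci,
        npv=npv,
        npv_ci=clopper_pearson(tn, tn + fn, level) if tn + fn > 0 else nan_ci,
    )


def youden_threshold(roc: RocResult, level: float = 0.95) -> ThresholdMetrics:
    """Cutpoint maximising the Youden index on the empirical ROC, with ties
    broken toward higher specificity (the larger cutpoint)."""
    if roc.scores is None or roc.labels is None:
        raise ValueError("RocResult must carry its scores and labels")
    j = roc.sensitivities + roc.specificities - 1
    best = 0
    for i in range(1, len(roc.thresholds)):
        if (j[i], roc.specificities[i]) > (j[best], roc.specificities[best]):
            best = i
    return threshold_metrics(
        roc.scores, roc.labels, roc.thresholds[best], "greater", level
    )


@dataclass(frozen=True)
class PublishedThreshold:
    """A reference cutpoint with its direction convention."""

    feature: str
    cutpoint: float
    direction: str


#: Reference cutpoints for the four discriminating parameters, with the
#: printed direction conventions (strict '>' except the stromal rule).
PUBLISHED_THRESHOLDS: tuple[PublishedThreshold, ...] = (
    PublishedThreshold("epi_reflectivity_mean", 142.9, "greater"),
    PublishedThreshold("stromal_reflectivity_mean", 151.8, "less_equal"),
    PublishedThreshold("reflectivity_ratio_mean", 1.29, "greater"),
    PublishedThreshold("mean_superficial_vd", 0.38, "greater"),
)
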