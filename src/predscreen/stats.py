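"""Statistical primitives shared by every pipeline stage.

The module bundles the estimators a trial-level/patient-level biomarker
analysis needs: back-calculation of log-HR standard errors from published
confidence intervals, DerSimonian-Laird random-effects pooling with the
I-squared heterogeneity summary, the normal subgroup-difference
(interaction) test, Fisher's exact test and Clopper-Pearson intervals for
response rates, Kaplan-Meier curves with the log-rank test, Cox
proportional-hazards fitting (Efron tie correction), Spearman rank
correlation, and two-group comparison (Wilcoxon rank-sum / Pearson chi2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._cox import efron_newton

__all__ = [
    "Z95",
    "HazardRatioEstimate",
    "PooledEstimate",
    "KMCurve",
    "CoxFit",
    "log_hr_from_ci",
    "pool_random_effects",
    "subgroup_difference_test",
    "fisher_exact",
    "clopper_pearson",
    "km_curve",
    "km_logrank",
    "fit_cox",
    "spearman",
    "group_compare",
]

#: exact 97.5% standard-normal quantile (not the rounded 1.96)
Z95 = float(sps.norm.ppf(0.975))


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# hazard-ratio containers


@dataclass(frozen=True)
class HazardRatioEstimate:
    """One subgroup hazard-ratio estimate with its 95% CI on both scales."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se_log_hr: float
    n: int | None = None

    def __post_init__(self):
        if not (0 < self.ci_low <= self.hr <= self.ci_high):
            raise ValidationError(
                f"require 0 < ci_low <= hr <= ci_high, got "
                f"({self.ci_low}, {self.hr}, {self.ci_high})"
            )
        if self.se_log_hr <= 0:
            raise ValidationError("se_log_hr must be positive (degenerate CI?)")
        if abs(self.log_hr - math.log(self.hr)) > 1e-12:
            raise ValidationError("log_hr inconsistent with hr")


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects pooled log hazard ratio with heterogeneity summary."""

    k: int
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    Q: float
    tau2: float
    I2: float


def log_hr_from_ci(hr: float, ci_low: float, ci_high: float,
                   n: int | None = None) -> HazardRatioEstimate:
    """Back-calculate the log-HR standard error from a published 95% CI.

    se = (ln ci_high - ln ci_low) / (2 * z_0.975), the standard
    meta-analytic reconstruction for symmetric log-scale intervals.
    """
    if hr <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValidationError("hazard ratios and CI bounds must be positive")
    if ci_low > ci_high:
        raise ValidationError(f"ci_low {ci_low} > ci_high {ci_high}")
    if not (ci_low <= hr <= ci_high):
        raise ValidationError("hr must lie inside its CI")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if se <= 0:
        raise ValidationError("degenerate CI (zero width)")
    return HazardRatioEstimate(hr=hr, ci_low=ci_low, ci_high=ci_high,
                               log_hr=math.log(hr), se_log_hr=se, n=n)


def _pooled_from(log_hr: float, se: float, k: int, Q: float, tau2: float,
                 I2: float) -> PooledEstimate:
    return PooledEstimate(
        k=k, log_hr=log_hr, se=se, hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - Z95 * se),
        ci_high=math.exp(log_hr + Z95 * se),
        Q=Q, tau2=tau2, I2=I2,
    )


def pool_random_effects(estimates: Sequence[HazardRatioEstimate]) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling of log hazard ratios.

    Fixed-effect weights w_i = 1/se_i^2 give the heterogeneity statistic
    Q = sum w_i (y_i - ybar_F)^2; the between-trial variance is
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(se_i^2 + tau2) give the pooled estimate.  A single estimate
    is returned unchanged with Q = 0, I2 = 0.
    """
    if len(estimates) == 0:
        raise ValidationError("cannot pool an empty list of estimates")
    y = np.array([e.log_hr for e in estimates])
    se = np.array([e.se_log_hr for e in estimates])
    k = len(y)
    if k == 1:
        return _pooled_from(float(y[0]), float(se[0]), 1, 0.0, 0.0, 0.0)
    w = 1.0 / se**2
    ybar_f = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar_f) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    log_hr = float(np.sum(w_star * y) / np.sum(w_star))
    se_pool = float(1.0 / math.sqrt(np.sum(w_star)))
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return _pooled_from(log_hr, se_pool, k, Q, tau2, I2)


def subgroup_difference_test(pos: PooledEstimate,
                             neg: PooledEstimate) -> tuple[float, float]:
    """Normal test on the difference of two pooled log hazard ratios.

    This is the standard fixed-effect subgroup-difference (interaction)
    test: z = (y_pos - y_neg) / sqrt(se_pos^2 + se_neg^2), two-sided p.
    """
    z = (pos.log_hr - neg.log_hr) / math.sqrt(pos.se**2 + neg.se**2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(max(p, np.nextafter(0, 1)), 1.0))


# ---------------------------------------------------------------------------
# exact tests for response rates


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("need a 2x2 table of non-negative counts")
    return t


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the minimum-likelihood convention (sum of
    hypergeometric probabilities no larger than the observed table's).
    """
    t = _as_2x2(table)
    if t.sum() == 0:
        raise ValidationError("all-zero 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def clopper_pearson(successes: int, n: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    if n < 1 or not (0 <= successes <= n):
        raise ValidationError(f"invalid counts ({successes}, {n})")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


# ---------------------------------------------------------------------------
# survival machinery


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier product-limit estimate."""

    times: np.ndarray          # distinct event times (ascending)
    survival: np.ndarray       # S(t) just after each event time
    n: int
    n_events: int
    median: float = math.nan   # first time S(t) <= 0.5; nan if never reached

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier estimate for one group (arrays of times and 0/1 events)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("empty survival group")
    if np.any(time <= 0):
        raise ValidationError("survival times must be positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event == 1])
    surv = []
    s = 1.0
    median = math.nan
    for t in ev_times:
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
        if math.isnan(median) and s <= 0.5:
            median = float(t)
    return KMCurve(times=ev_times, survival=np.array(surv), n=int(time.size),
                   n_events=int(event.sum()), median=median)


def km_logrank(time_a, event_a, time_b, event_b):
    """KM curves for two groups plus the one-df log-rank test.

    Returns ``(curve_a, curve_b, chi2, p)``; the test statistic and p are
    NaN when neither group has any event (test undefined).
    """
    curve_a = km_curve(time_a, event_a)
    curve_b = km_curve(time_b, event_b)
    if curve_a.n_events == 0 and curve_b.n_events == 0:
        return curve_a, curve_b, math.nan, math.nan

    time = np.concatenate([np.asarray(time_a, float), np.asarray(time_b, float)])
    event = np.concatenate([np.asarray(event_a, int), np.asarray(event_b, int)])
    grp = np.concatenate([np.zeros(len(np.atleast_1d(time_a)), int),
                          np.ones(len(np.atleast_1d(time_b)), int)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d_t = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (grp == 0)).sum()
        e1 = d_t * n1 / n_t
        o_minus_e += d1 - e1
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if var <= 0:
        return curve_a, curve_b, math.nan, math.nan
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return curve_a, curve_b, float(chi2), p


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit (Efron tie correction)."""

    summary: pd.DataFrame      # index: covariate; coef, se, z, p, hr, ci_low, ci_high
    converged: bool
    n: int
    n_events: int
    loglik: float = math.nan

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


def fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: Sequence[str]) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Coefficients maximize the partial likelihood with the Efron correction
    for tied event times; standard errors come from the inverse observed
    information.  Non-convergence (including monotone-likelihood
    separation) is reported via ``converged=False`` with NaN inference
    columns — downstream consumers must treat such fits as not estimable.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValidationError("no covariates supplied")
    sub = df[[duration_col, event_col, *covariates]].dropna()
    x = sub[covariates].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(x[:, j]) == 0:
            raise ValidationError(f"covariate '{name}' is constant")
    time = sub[duration_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    if np.unique(time[event == 1]).size < 2:
        raise ValidationError("need at least 2 distinct event times")
    res = efron_newton(x, time, event)
    coef, se = res["coef"], res["se"]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = coef / se
        p = 2.0 * sps.norm.sf(np.abs(z))
        summary = pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "z": z,
                "p": p,
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - Z95 * se),
                "ci_high": np.exp(coef + Z95 * se),
            },
            index=pd.Index(covariates, name="covariate"),
        )
    return CoxFit(summary=summary, converged=bool(res["converged"]),
                  n=int(len(sub)), n_events=int(event.sum()),
                  loglik=float(res["loglik"]))


# ---------------------------------------------------------------------------
# correlation and two-group comparison


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for Spearman rho by full enumeration (small n)."""
    n = len(rx)
    rx = rx - rx.mean()
    denom_x = math.sqrt(np.sum(rx**2))
    perms = np.array(list(itertools.permutations(ry)))
    perms = perms - ry.mean()
    denom_y = math.sqrt(np.sum((ry - ry.mean()) ** 2))
    rhos = perms @ rx / (denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value uses the t-approximation for n >= 10 and an exact
    permutation enumeration for n < 10.  Constant input yields
    ``(nan, nan)`` (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n >= 10:
        # t-approximation: t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    else:
        p = _exact_spearman_p(rx, ry, rho)
    return rho, min(p, 1.0)


def group_compare(a, b, kind: str = "auto") -> float:
    """Two-group comparison p-value.

    Continuous data -> two-sided Wilcoxon rank-sum (midranks, normal
    approximation with tie correction); categorical data -> Pearson chi2
    on the 2 x levels contingency table.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if kind == "auto":
        kind = "continuous" if (np.issubdtype(a.dtype, np.number)
                                and np.issubdtype(b.dtype, np.number)) else "categorical"
    if kind == "continuous":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        return float(res.pvalue)
    if kind == "categorical":
        levels = np.unique(np.concatenate([a, b]))
        table = np.array([[np.sum(a == lv) for lv in levels],
                          [np.sum(b == lv) for lv in levels]])
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p)
    raise ValidationError(f"unknown kind '{kind}'")
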