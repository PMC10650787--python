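"""Group statistics: one-way ANOVA with Tukey HSD and eta-squared CIs,
and paired t-tests, matching small-animal PET reporting conventions.

eta^2 = SS_between / SS_total; its 95% CI comes from inverting the
noncentral-F distribution (Steiger's method): the confidence bounds on the
noncentrality parameter lambda map to eta^2 = lambda / (lambda + df1 + df2 + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    eta_squared: float
    eta_squared_ci: tuple[float, float]
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    df: int
    p_value: float


def _eta_sq_from_lambda(lam: float, df1: int, df2: int) -> float:
    return lam / (lam + df1 + df2 + 1)


def _lambda_bound(f_obs: float, df1: int, df2: int, prob: float) -> float:
    """Noncentrality lambda such that P(F <= f_obs | lambda) = prob."""

    def g(lam):
        return sps.ncf.cdf(f_obs, df1, df2, lam) - prob

    if g(0.0) < 0:  # even the central F puts too little mass below f_obs
        return 0.0
    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return brentq(g, 0.0, hi, xtol=1e-10)


def anova_with_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with post hoc Tukey HSD and eta^2 with a 95% CI."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_total = float(np.sum((all_vals - grand) ** 2))
    ss_within = ss_total - ss_between
    k = len(arrays)
    n = all_vals.size
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        f_obs = 0.0 if ss_between <= 0 else np.inf
        p = 1.0 if f_obs == 0.0 else 0.0
    else:
        f_obs = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f_obs, df1, df2))
    eta_sq = 0.0 if ss_total == 0 else ss_between / ss_total

    if np.isfinite(f_obs):
        lam_lo = _lambda_bound(f_obs, df1, df2, 1 - alpha / 2)
        lam_hi = _lambda_bound(f_obs, df1, df2, alpha / 2)
        ci = (_eta_sq_from_lambda(lam_lo, df1, df2), _eta_sq_from_lambda(lam_hi, df1, df2))
    else:
        ci = (eta_sq, 1.0)

    tk = pairwise_tukeyhsd(all_vals, labels, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return GroupComparison(
        f_statistic=float(f_obs), df=(df1, df2), p_value=p,
        eta_squared=float(eta_sq), eta_squared_ci=ci, tukey=tukey,
    )


def paired_compare(x, y) -> PairedComparison:
    """Paired t-test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d samples with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedComparison(t_statistic=0.0, df=n - 1, p_value=1.0)
        warnings.warn(
            "zero-variance nonzero differences: t is an infinite sentinel",
            RuntimeWarning, stacklevel=2,
        )
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedComparison(t_statistic=t, df=n - 1, p_value=0.0)
    res = sps.ttest_rel(x, y)
    return PairedComparison(
        t_statistic=float(res.statistic), df=n - 1, p_value=float(res.pvalue)
    )
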