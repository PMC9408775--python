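"""One-way ANOVA with Scheffe post hoc, simple linear regression,
percent-of-control transforms.

All tail probabilities go through the regularized incomplete beta function
(scipy.special.betainc):

    P(F > f | d1, d2) = I_{d2/(d2 + d1 f)}(d2/2, d1/2)
    P(|T| > t | df)   = I_{df/(df + t^2)}(df/2, 1/2)

The Scheffe criterion for the pairwise contrast (i, j) is

    F_S = (m_i - m_j)^2 / (MS_within (1/n_i + 1/n_j))
    significant  <=>  F_S > (k - 1) F_{alpha, k-1, N-k}

which holds the familywise error over all contrasts at alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import betainc, betaincinv

__all__ = [
    "AnovaResult",
    "ScheffeContrast",
    "RegressionResult",
    "one_way_anova",
    "scheffe_posthoc",
    "linear_regression",
    "percent_of_control",
    "f_sf",
    "t_sf_two_sided",
    "f_isf",
]

DEFAULT_ALPHA = 0.05


def f_sf(f: float, d1: float, d2: float) -> float:
    """Upper tail P(F > f) of the F distribution via the incomplete beta."""
    if f <= 0:
        return 1.0
    return float(betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * f)))


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided P(|T| > t) of Student's t via the incomplete beta."""
    if t == 0:
        return 1.0
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def f_isf(p: float, d1: float, d2: float) -> float:
    """Upper-tail F quantile, inverting the incomplete-beta representation."""
    x = float(betaincinv(d2 / 2.0, d1 / 2.0, p))
    return d2 * (1.0 - x) / (d1 * x)


@dataclass
class AnovaResult:
    k: int
    n_total: int
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: tuple
    group_ns: tuple
    degenerate: bool = False  # zero within-variance with unequal means


@dataclass
class ScheffeContrast:
    pair: tuple  # (i, j) group indices
    mean_difference: float
    f_scheffe: float
    critical: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    t: float
    p: float


def _as_groups(groups):
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError("every group needs n >= 2 for the within degrees of freedom")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite value in a group")
        out.append(arr)
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical between/within decomposition over ``groups``.

    Identical constant groups give F = 0, p = 1; zero within-variance with
    unequal means is reported as the p = 0 boundary with ``degenerate`` set.
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w

    degenerate = False
    if ms_within == 0.0:
        if ms_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, degenerate = math.inf, 0.0, True
    else:
        f_stat = ms_between / ms_within
        p = f_sf(f_stat, df_b, df_w)
    return AnovaResult(
        k=k, n_total=n_total, f=f_stat, df_between=df_b, df_within=df_w,
        p=p, ms_within=ms_within,
        group_means=tuple(means), group_ns=tuple(int(n) for n in ns),
        degenerate=degenerate,
    )


def scheffe_posthoc(anova: AnovaResult, groups, alpha: float = DEFAULT_ALPHA):
    """All pairwise Scheffe contrasts for the fitted ANOVA.

    ``groups`` must be the samples the ANOVA was computed on (checked via
    group sizes and means).
    """
    gs = _as_groups(groups)
    if len(gs) != anova.k:
        raise ValueError("group count does not match the ANOVA")
    for g, m, n in zip(gs, anova.group_means, anova.group_ns):
        if g.size != n or not math.isclose(g.mean(), m, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("groups do not match the ANOVA they are tested against")

    critical = (anova.k - 1) * f_isf(alpha, anova.df_between, anova.df_within)
    out = []
    for i, j in combinations(range(anova.k), 2):
        diff = anova.group_means[i] - anova.group_means[j]
        denom = anova.ms_within * (1.0 / anova.group_ns[i] + 1.0 / anova.group_ns[j])
        if denom == 0.0:
            f_s = 0.0 if diff == 0 else math.inf
        else:
            f_s = diff * diff / denom
        out.append(ScheffeContrast(
            pair=(i, j), mean_difference=float(diff), f_scheffe=float(f_s),
            critical=float(critical), significant=bool(f_s > critical), alpha=alpha,
        ))
    return out


def linear_regression(x, y) -> RegressionResult:
    """Least-squares line with the t test for a non-zero slope."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for the slope test")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("x is constant: slope is singular")
    syy = float(((y - y.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        r = 0.0
    else:
        r = sxy / math.sqrt(sxx * syy)
    r2 = r * r
    df = n - 2
    if 1.0 - r2 <= 0.0:
        t_stat, p = math.inf, 0.0
    else:
        t_stat = r * math.sqrt(df / (1.0 - r2))
        p = t_sf_two_sided(t_stat, df)
    return RegressionResult(slope=float(slope), intercept=intercept, r=float(r),
                            r2=float(r2), n=int(n), t=float(t_stat), p=float(p))


def percent_of_control(group_mean: float, group_sem: float, control_mean: float):
    """(100 * mean / control, 100 * sem / control); control must be > 0."""
    if not control_mean > 0:
        raise ValueError("control mean must be > 0 for percent-of-control scaling")
    return 100.0 * group_mean / control_mean, 100.0 * group_sem / control_mean


def sem(values) -> float:
    """Standard error of the mean (ddof=1; 0 for a single value)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        return 0.0
    return float(arr.std(ddof=1) / math.sqrt(arr.size))
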