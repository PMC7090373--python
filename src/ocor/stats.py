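"""Statistical kernels used by the timecourse analysis.

Hand-written closed forms (paired t, one-way within-subject ANOVA, exact
Mann-Whitney enumeration, Tukey-style quartiles); scipy supplies only the
reference distributions and the Shapiro-Wilk routine. The kernels are
deliberately small and transparent so they can be checked against
brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import OcorError

__all__ = [
    "PairedTResult",
    "RMAnovaResult",
    "paired_t",
    "rm_anova",
    "mann_whitney",
    "normality_check",
    "tukey_quartiles",
]

EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate_variance: bool = False


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    p: float
    df_time: int
    df_error: int
    ss_time: float
    ss_error: float
    ss_subject: float


def paired_t(diffs: Sequence[float]) -> PairedTResult:
    """Two-sided paired t test on a vector of within-pair differences.

    Zero-variance differences are degenerate: the t statistic is ±∞ (p = 0)
    for a non-zero constant difference, and 0 (p = 1) when all differences
    vanish; both are flagged.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise OcorError("paired t test requires at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, df=n - 1, mean_diff=0.0, degenerate_variance=True)
        t = math.inf if mean > 0 else -math.inf
        return PairedTResult(t=t, p=0.0, df=n - 1, mean_diff=mean, degenerate_variance=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, p=p, df=n - 1, mean_diff=mean)


def rm_anova(data: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on an n-subjects × k-times matrix.

    F = MS_time / MS_error with (k−1) and (n−1)(k−1) degrees of freedom,
    from the standard within-subject sums-of-squares decomposition.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise OcorError("rm_anova expects a 2-D subjects × times matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise OcorError("rm_anova requires at least 2 subjects and 2 timepoints")
    if np.isnan(x).any():
        raise OcorError("rm_anova requires complete cases (listwise-delete first)")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    time_means = x.mean(axis=0)
    ss_subject = k * float(((subj_means - grand) ** 2).sum())
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_time, 0.0)
    df_time = k - 1
    df_error = (n - 1) * (k - 1)
    if ss_time <= 1e-12 * max(ss_total, 1.0):
        f, p = 0.0, 1.0
    elif ss_error == 0.0:
        f, p = math.inf, 0.0
    else:
        f = (ss_time / df_time) / (ss_error / df_error)
        p = float(sps.f.sf(f, df_time, df_error))
    return RMAnovaResult(
        f=f, p=p, df_time=df_time, df_error=df_error,
        ss_time=ss_time, ss_error=ss_error, ss_subject=ss_subject,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # pairwise comparison count; ties count one half
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group A, p).

    Small samples (≤ 8 per group) use exact enumeration of all
    C(n+m, n) group assignments of the pooled values; larger samples use
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise OcorError("mann_whitney requires two non-empty groups")
    u = _u_statistic(a, b)

    if n <= EXACT_MW_MAX_N and m <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        total = 0
        le = 0
        ge = 0
        idx = np.arange(n + m)
        for combo in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u_star = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u_star <= u + 1e-12:
                le += 1
            if u_star >= u - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u, p

    big = np.concatenate([a, b])
    big_n = n + m
    mu = n * m / 2.0
    _, counts = np.unique(big, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if sigma2 <= 0:
        return u, 1.0  # all values tied
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return u, p


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test for normality; (W, p). Valid for 3 ≤ n ≤ 50."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 50:
        raise OcorError("normality_check supports 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise OcorError("normality_check undefined for a constant vector")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def tukey_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the midpoint-of-halves convention.

    The data are split at the median (which is excluded from both halves
    when n is odd); Q1/Q3 are the medians of the halves.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise OcorError("quartiles require at least 3 values")
    med = float(np.median(x))
    half = n // 2
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3
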