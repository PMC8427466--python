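"""The study's statistical layer.

Bland-Altman agreement with 95% limits of agreement, inter-subject
coefficients of variation compared with Forkman's F test, Welch's unpaired
t test (from raw samples or printed mean/SE/n summaries), Mann-Whitney U
for non-normal samples, Kolmogorov-Smirnov normality with parameters
estimated from the sample (Lilliefors-corrected null by seeded Monte
Carlo), a 2 (sham/BDL) x 2 (baseline/post-LPS) split-plot mixed ANOVA with
Bonferroni post hoc tests, and attrition-adjusted sample-size inflation.

All tests are two-sided.  Summary-based entry points take standard errors
(the convention used when results are reported as mean +/- SE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class GroupSummary(NamedTuple):
    """Printed group summary: mean, standard error, group size."""

    mean: float
    se: float
    n: int


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(method_a, method_b=None) -> AgreementResult:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    Accepts two paired samples, or a single (n, 2) array of pairs.  The
    limits are bias +/- 1.96 x sample SD of the differences (the large-
    sample multiplier, not a small-sample t quantile).
    """
    if method_b is None:
        pairs = np.asarray(method_a, float)
        a, b = pairs[:, 0], pairs[:, 1]
    else:
        a = np.asarray(method_a, float)
        b = np.asarray(method_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, n=len(d))


# --------------------------------------------------------------------------
# Coefficient of variation and Forkman's equality test
# --------------------------------------------------------------------------

def coefficient_of_variation(sample) -> float:
    """Inter-subject coefficient of variation in percent: 100 * SD / mean."""
    x = np.asarray(sample, float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass(frozen=True)
class CovTestResult:
    cov1_pct: float
    cov2_pct: float
    F: float
    df1: int
    df2: int
    p_two_sided: float


def forkman_cov_test(cov1: float, n1: int, cov2: float, n2: int) -> CovTestResult:
    """Forkman's F test for equality of two coefficients of variation.

    ``cov1``/``cov2`` are CoVs as fractions (0.293 for 29.3%).  The statistic

        F = [c1^2 / (1 + c1^2 (n1-1)/n1)] / [c2^2 / (1 + c2^2 (n2-1)/n2)]

    is referred to an F(n1-1, n2-1) distribution; the two-sided p-value is
    2 * min(P(F <= f), P(F >= f)).
    """
    if cov1 <= 0 or cov2 <= 0:
        raise ValueError("CoVs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    c1s, c2s = cov1 ** 2, cov2 ** 2
    num = c1s / (1.0 + c1s * (n1 - 1) / n1)
    den = c2s / (1.0 + c2s * (n2 - 1) / n2)
    F = num / den
    df1, df2 = n1 - 1, n2 - 1
    p = 2.0 * min(sps.f.cdf(F, df1, df2), sps.f.sf(F, df1, df2))
    return CovTestResult(cov1_pct=100.0 * cov1, cov2_pct=100.0 * cov2, F=float(F),
                         df1=df1, df2=df2, p_two_sided=float(min(1.0, p)))


def forkman_from_samples(sample1, sample2) -> CovTestResult:
    """Forkman's test computed from two raw samples."""
    x, y = np.asarray(sample1, float), np.asarray(sample2, float)
    return forkman_cov_test(coefficient_of_variation(x) / 100.0, len(x),
                            coefficient_of_variation(y) / 100.0, len(y))


# --------------------------------------------------------------------------
# Welch's t test
# --------------------------------------------------------------------------

def _as_summary(sample) -> GroupSummary:
    if isinstance(sample, GroupSummary):
        return sample
    if isinstance(sample, tuple) and len(sample) == 3:
        return GroupSummary(*sample)
    x = np.asarray(sample, float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations per group")
    return GroupSummary(float(x.mean()), float(x.std(ddof=1) / math.sqrt(len(x))),
                        len(x))


def welch_t(sample_or_summary_1, sample_or_summary_2):
    """Welch's unpaired t test from samples or (mean, SE, n) summaries.

    Returns ``(t, df, p_two_sided)`` with the Welch-Satterthwaite degrees
    of freedom.  Summaries reported as mean +/- SE can be passed
    directly as ``GroupSummary(mean, se, n)`` tuples.
    """
    g1 = _as_summary(sample_or_summary_1)
    g2 = _as_summary(sample_or_summary_2)
    v1, v2 = g1.se ** 2, g2.se ** 2
    if v1 + v2 == 0:
        raise ValueError("both groups have zero variance")
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def mann_whitney_u(sample1, sample2):
    """Two-sided Mann-Whitney U test.

    Exact enumeration p-value for small pooled samples (n1 + n2 <= 20,
    no ties); normal approximation with tie correction otherwise.
    Returns ``(U, p_two_sided)`` with U the statistic of the first sample.
    """
    x = np.asarray(sample1, float)
    y = np.asarray(sample2, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov normality (Lilliefors-corrected)
# --------------------------------------------------------------------------

def _lilliefors_statistic(z_sorted: np.ndarray) -> float:
    n = len(z_sorted)
    cdf = sps.norm.cdf(z_sorted)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def ks_normality(sample, n_mc: int = 10_000, seed: int = 0):
    """KS normality test with mean/SD estimated from the sample.

    The statistic is D = sup |empirical CDF - fitted normal CDF|; because
    the null parameters are estimated, the p-value comes from a seeded
    Monte-Carlo null (Lilliefors correction) with ``n_mc`` replicates.
    Returns ``(D, p)``.
    """
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    D = _lilliefors_statistic((x - x.mean()) / sd)

    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    mu = sims.mean(axis=1, keepdims=True)
    s = sims.std(axis=1, ddof=1, keepdims=True)
    z = (sims - mu) / s
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_null = np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n), axis=1)
    p = (1 + np.sum(d_null >= D)) / (n_mc + 1)
    return float(D), float(p)


# --------------------------------------------------------------------------
# 2x2 split-plot (mixed) ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f_interaction: float
    df1: int
    df2: int
    p_interaction: float
    group_changes: dict          # group -> (mean change, SE, n)
    posthoc: dict                # group -> (t, df, p_raw, p_bonferroni)
    dropped_subjects: tuple


def mixed_anova_2x2(records) -> AnovaResult:
    """Split-plot ANOVA for a 2 (between-group) x 2 (within-subject) design.

    ``records`` is a tidy table (DataFrame or iterable of tuples) with
    columns (subject, group, time, value); each subject must appear at both
    time points, and exactly two groups and two time levels must be present.
    Subjects missing a time point are dropped with a warning (mirroring
    study attrition).

    For this design the group x time interaction F with df (1, n - 2)
    equals the squared pooled-variance two-sample t statistic on the
    per-subject change scores, which handles unbalanced groups exactly.
    Post hoc per-group paired comparisons (baseline vs follow-up) are
    Bonferroni-adjusted for the two comparisons.
    """
    df = records if isinstance(records, pd.DataFrame) else \
        pd.DataFrame(records, columns=["subject", "group", "time", "value"])
    df = df[["subject", "group", "time", "value"]].copy()
    groups = sorted(df["group"].unique())
    times = sorted(df["time"].unique())
    if len(groups) != 2 or len(times) != 2:
        raise ValueError("design must have exactly 2 groups and 2 time points")

    wide = df.pivot_table(index=["subject", "group"], columns="time",
                          values="value", aggfunc="first")
    complete = wide.dropna()
    dropped = tuple(s for s, _ in wide.index.difference(complete.index))
    if dropped:
        warnings.warn(f"dropping subjects missing a time point: {dropped}",
                      stacklevel=2)
    change = complete[times[1]] - complete[times[0]]
    by_group = {g: change.xs(g, level="group").to_numpy() for g in groups}
    n1, n2 = len(by_group[groups[0]]), len(by_group[groups[1]])
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 complete subjects per group")

    d1, d2 = by_group[groups[0]], by_group[groups[1]]
    sp2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        F = 0.0 if d1.mean() == d2.mean() else np.inf
    else:
        t = (d1.mean() - d2.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        F = t * t
    df2 = n1 + n2 - 2
    p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0

    group_changes = {}
    posthoc = {}
    for g, d in by_group.items():
        n = len(d)
        se = d.std(ddof=1) / math.sqrt(n)
        group_changes[g] = (float(d.mean()), float(se), n)
        if se == 0:
            t_g, p_raw = (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
        else:
            t_g = d.mean() / se
            p_raw = 2.0 * sps.t.sf(abs(t_g), n - 1)
        posthoc[g] = (float(t_g), n - 1, float(p_raw), float(min(1.0, 2.0 * p_raw)))

    return AnovaResult(f_interaction=float(F), df1=1, df2=df2, p_interaction=p,
                       group_changes=group_changes, posthoc=posthoc,
                       dropped_subjects=dropped)


# --------------------------------------------------------------------------
# Sample size
# --------------------------------------------------------------------------

def attrition_inflate(n_required: int, attrition_rate: float) -> int:
    """Inflate a required sample size for an expected attrition rate.

    ceil(n / (1 - rate)): the group size to recruit so that the expected
    number of completers is at least ``n_required``.
    """
    if not (0.0 <= attrition_rate < 1.0):
        raise ValueError("attrition rate must lie in [0, 1)")
    if n_required < 1:
        raise ValueError("required sample size must be positive")
    return math.ceil(n_required / (1.0 - attrition_rate))
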