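"""Normality-gated two-group comparison and correlation.

The comparison procedure mirrors classical bench-statistics practice:
every endpoint is first screened for normality with a Lilliefors-corrected
Kolmogorov-Smirnov test in each group; if both groups pass, an unpaired
pooled-variance Student's t test is used, otherwise the Mann-Whitney rank
sum test (exact by enumeration for small samples).  Differences are called
significant at P < 0.05.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .clearance import fold_change
from .cohort import ValidationError

__all__ = [
    "GroupComparison",
    "lilliefors_ks",
    "compare_groups",
    "mann_whitney_exact",
    "pearson_r",
    "SIGNIFICANCE_ALPHA",
]

SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    fold_change: float
    normality_p_a: float
    normality_p_b: float
    significant: bool


def _lilliefors_distance(sample: np.ndarray) -> float:
    """KS distance of a sample against Normal(mean-hat, sd-hat)."""
    n = sample.size
    z = np.sort((sample - sample.mean()) / sample.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def lilliefors_ks(sample: Sequence[float], n_mc: int = 10_000, seed: int = 0) -> float:
    """Lilliefors-corrected KS normality test, Monte-Carlo P value.

    The null distribution of the KS distance with estimated mean and SD is
    simulated: ``n_mc`` standard-normal samples of the same size, each
    re-standardised with its own estimates.  The P value is
    ``(1 + #{D_null >= D_obs}) / (n_mc + 1)``, seeded and reproducible for
    any sample size.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValidationError("normality test requires at least 4 values")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate sample")
    d_obs = _lilliefors_distance(x)
    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((int(n_mc), n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort(sims, axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_null = np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n), axis=1)
    return float((1 + np.sum(d_null >= d_obs)) / (n_mc + 1))


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by enumeration of all rank assignments.

    Enumerates every split of the pooled sample into groups of the
    observed sizes (midranks for ties, conditional on the observed data),
    returning the U statistic of the first group and
    ``P = #{|U - mu| >= |U_obs - mu|} / C(n_a + n_b, n_a)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    mu = na * nb / 2.0
    total = 0
    extreme = 0
    for comb in combinations(range(na + nb), na):
        u = float(np.sum(ranks[list(comb)]) - na * (na + 1) / 2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_normality: float = 0.05,
    normality_n_mc: int = 10_000,
    seed: int = 0,
    exact_max_n: int = 12,
    welch: bool = False,
) -> GroupComparison:
    """Normality-gated unpaired two-group comparison.

    Both groups must pass the Lilliefors normality screen at
    ``alpha_normality`` for the Student's t test (pooled variance unless
    ``welch=True``); otherwise the Mann-Whitney rank sum test is used,
    exact by enumeration when the combined sample size is at most
    ``exact_max_n`` and tie-corrected normal approximation beyond.
    The attached fold-change is mean(a)/mean(b).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    try:
        p_na = lilliefors_ks(x, normality_n_mc, seed)
        p_nb = lilliefors_ks(y, normality_n_mc, seed + 1)
        normal = p_na >= alpha_normality and p_nb >= alpha_normality
    except ValidationError:
        # too small or constant: the rank test is the only defensible route
        p_na = p_nb = float("nan")
        normal = False
    fc = fold_change(x, y)
    if normal:
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        used = "student_t"
    elif x.size + y.size <= exact_max_n:
        stat, p = mann_whitney_exact(x, y)
        used = "mann_whitney"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        used = "mann_whitney"
    p = float(min(p, 1.0))
    return GroupComparison(
        test_used=used,
        statistic=float(stat),
        p_value=p,
        fold_change=fc,
        normality_p_a=float(p_na),
        normality_p_b=float(p_nb),
        significant=bool(p < SIGNIFICANCE_ALPHA),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided P from the t transform."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValidationError("need equal-length samples of at least 3 values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("constant input")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p)
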