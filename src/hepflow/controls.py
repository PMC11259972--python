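"""Nonparametric control comparisons of cardiac measures.

Wilcoxon signed-rank (paired pre/post contrasts) and Mann–Whitney U
(independent group contrasts) with the reporting conventions used for
the cardiac control table: the Z statistic from the tie-corrected
normal approximation, medians with interquartile ranges per condition,
and the rank-biserial-style effect size r = Z/√(2n) for paired and
r = Z/√N for independent comparisons.  Exact p-values by enumeration
are available for small samples and are used as the internal oracle.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "normality_check",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "paired_effect_size_r",
    "independent_effect_size_r",
    "NormalityDecision",
    "WilcoxonResult",
    "MannWhitneyResult",
]


def paired_effect_size_r(z: float, n_pairs: int) -> float:
    """Effect size r = Z / sqrt(2 n) for a paired rank comparison."""
    return z / math.sqrt(2 * n_pairs)


def independent_effect_size_r(z: float, n_total: int) -> float:
    """Effect size r = Z / sqrt(N) for an independent rank comparison."""
    return z / math.sqrt(n_total)


@dataclass(frozen=True)
class NormalityDecision:
    """Routing decision from a Shapiro–Wilk check."""

    parametric: bool
    p_value: float
    statistic: float


def normality_check(sample: np.ndarray, alpha: float = 0.05) -> NormalityDecision:
    """Shapiro–Wilk at ``alpha``; nonparametric route on rejection.

    A constant sample cannot be tested and is routed nonparametric
    with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality check requires n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: routing nonparametric", stacklevel=2)
        return NormalityDecision(False, 0.0, math.nan)
    stat, p = stats.shapiro(x)
    return NormalityDecision(bool(p >= alpha), float(p), float(stat))


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) with linear-interpolation quartiles."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), (float(q1), float(q3))


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank comparison of paired samples."""

    z: float
    p_value: float
    r: float
    n_pairs: int
    n_nonzero: int
    w_plus: float
    median_pre: float
    iqr_pre: tuple[float, float]
    median_post: float
    iqr_post: tuple[float, float]
    method: str
    degenerate: bool = False


def _signed_rank_stat(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive ranks) and the tie-averaged ranks of |d|."""
    ranks = stats.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), ranks


def _wilcoxon_exact_p(diffs: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all sign assignments."""
    _, ranks = _signed_rank_stat(diffs)
    m = ranks.size
    total = 2**m
    ge = le = 0
    for bits in itertools.product((0, 1), repeat=m):
        w = float(np.dot(bits, ranks))
        if w >= w_plus - 1e-12:
            ge += 1
        if w <= w_plus + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def wilcoxon_signed_rank(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    method: str = "auto",
    exact_limit: int = 12,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of pre versus post.

    Zero differences are dropped before ranking.  Z uses the normal
    approximation with tie-corrected variance and no continuity
    correction, signed so that pre > post gives positive Z.  The
    effect size is r = Z/√(2n) with n the number of pairs supplied.
    ``method="exact"`` (or ``"auto"`` with few nonzero pairs)
    additionally computes the two-sided p by full enumeration of sign
    assignments.  If every difference is zero the comparison is
    degenerate and Z undefined.
    """
    pre = np.asarray(x_pre, dtype=float)
    post = np.asarray(x_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    n_pairs = pre.size
    if n_pairs < 5 and method != "exact":
        warnings.warn("normal approximation unreliable below 5 pairs",
                      stacklevel=2)
    med_pre, iqr_pre = _median_iqr(pre)
    med_post, iqr_post = _median_iqr(post)

    diffs = pre - post
    diffs = diffs[diffs != 0]
    m = diffs.size
    if m == 0:
        return WilcoxonResult(
            math.nan, 1.0, math.nan, n_pairs, 0, math.nan,
            med_pre, iqr_pre, med_post, iqr_post, "degenerate", True,
        )

    w_plus, ranks = _signed_rank_stat(diffs)
    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        z = math.nan
        p_approx = 1.0
    else:
        z = (w_plus - mu) / math.sqrt(sigma2)
        p_approx = 2.0 * stats.norm.sf(abs(z))

    use_exact = method == "exact" or (method == "auto" and m <= exact_limit)
    if use_exact:
        p = _wilcoxon_exact_p(diffs, w_plus)
        used = "exact"
    else:
        p = p_approx
        used = "approx"
    r = z / math.sqrt(2 * n_pairs) if np.isfinite(z) else math.nan
    return WilcoxonResult(
        float(z), float(p), float(r), n_pairs, m, w_plus,
        med_pre, iqr_pre, med_post, iqr_post, used,
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    """Rank-sum comparison of two independent groups."""

    u: float
    z: float
    p_value: float
    r: float
    n_a: int
    n_b: int
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    method: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A: pairs where a > b, ties counted half."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = float(ranks[: a.size].sum())
    return r_a - a.size * (a.size + 1) / 2.0


def _mannwhitney_exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    idx = set(range(n))
    ge = le = total = 0
    for combo in itertools.combinations(range(n), n_a):
        rest = list(idx - set(combo))
        u = _u_statistic(pooled[list(combo)], pooled[rest])
        total += 1
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def mann_whitney_u(
    x_group_a: np.ndarray,
    x_group_b: np.ndarray,
    method: str = "auto",
    exact_limit: int = 8,
) -> MannWhitneyResult:
    """Mann–Whitney U test of group A versus group B.

    U counts pairs where A exceeds B (ties half); Z is the
    tie-corrected normal approximation without continuity correction,
    negative when group A tends to rank lower.  Effect size
    r = Z/√(n_A + n_B).  Exact p by enumeration when both groups are
    small (``method="auto"``) or on request.
    """
    a = np.asarray(x_group_a, dtype=float)
    b = np.asarray(x_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    combined = np.concatenate([a, b])
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        z, p_approx = math.nan, 1.0
    else:
        z = (u - mu) / math.sqrt(sigma2)
        p_approx = 2.0 * stats.norm.sf(abs(z))

    use_exact = method == "exact" or (
        method == "auto" and max(n_a, n_b) <= exact_limit
    )
    if use_exact:
        p = _mannwhitney_exact_p(a, b, u)
        used = "exact"
    else:
        p, used = p_approx, "approx"
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    r = z / math.sqrt(n) if np.isfinite(z) else math.nan
    return MannWhitneyResult(
        float(u), float(z), float(p), float(r), n_a, n_b,
        med_a, iqr_a, med_b, iqr_b, used,
    )
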