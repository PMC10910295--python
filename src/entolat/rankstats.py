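"""Rank-based statistics for two-factor designs.

Implements the nonparametric toolbox used throughout the analysis:

* :func:`rank_with_ties` — mid-rank (tie-averaged) ranking, the shared
  primitive of everything below.
* :func:`scheirer_ray_hare` — the Scheirer-Ray-Hare test, a rank-based
  extension of the Kruskal-Wallis test to factorial designs.  Each effect's
  statistic is H = SS_effect / MS_total computed on the joint ranks, referred
  to a chi-square distribution; dividing by the total rank mean square absorbs
  the tie correction.
* :func:`kruskal_eta_squared` — the eta-squared effect size derived from a
  Kruskal-Wallis-type H statistic, eta2 = (H - k + 1) / (n - k).
* :func:`dunn_posthoc` — Dunn's pairwise z-tests on mean joint ranks with tie
  correction, optionally Bonferroni-adjusted over the requested comparisons.
* :func:`wilcoxon_ranksum_cc` — the two-sided Wilcoxon rank-sum (Mann-Whitney)
  test with tie-corrected normal approximation and 0.5 continuity correction.
* :func:`two_proportion_z` — pooled-variance two-proportion z-test.

All procedures are deterministic and depend only on the ranks of the data, so
every statistic is invariant under strictly monotone transformations of the
values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "FactorialSample",
    "SRHResult",
    "DunnComparison",
    "DunnResult",
    "rank_with_ties",
    "scheirer_ray_hare",
    "kruskal_eta_squared",
    "eta_squared_label",
    "dunn_posthoc",
    "wilcoxon_ranksum_cc",
    "two_proportion_z",
]


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Return 1-based ranks with ties assigned the average of spanned ranks.

    The rank sum is always N(N+1)/2.  Raises ``ValueError`` on empty input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty sequence")
    order = np.argsort(v, kind="stable")
    sv = v[order]
    new_group = np.concatenate(([True], sv[1:] != sv[:-1]))
    start = np.flatnonzero(new_group)  # 0-based start of each tie group
    end = np.append(start[1:], v.size)  # one past its last position
    avg_rank = 0.5 * (start + end - 1) + 1.0  # mean of spanned 1-based ranks
    ranks = np.empty(v.size, dtype=float)
    ranks[order] = avg_rank[np.cumsum(new_group) - 1]
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


@dataclass(frozen=True)
class FactorialSample:
    """One dependent variable per unit with its two crossed factor levels."""

    values: np.ndarray
    factor_a: np.ndarray  # e.g. treatment: dark / light
    factor_b: np.ndarray  # e.g. hemisphere: left / right

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        a = np.asarray(self.factor_a)
        b = np.asarray(self.factor_b)
        if not (len(v) == len(a) == len(b)):
            raise ValueError("values and factor labels must have equal length")
        if len(v) == 0:
            raise ValueError("empty sample")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "factor_a", a)
        object.__setattr__(self, "factor_b", b)


@dataclass(frozen=True)
class SRHResult:
    """Scheirer-Ray-Hare statistics for main effects A, B and interaction."""

    H_a: float
    H_b: float
    H_ab: float
    df_a: int
    df_b: int
    df_ab: int
    p_a: float
    p_b: float
    p_ab: float
    eta2_a: float
    eta2_b: float
    eta2_ab: float
    n: int


def _dummy(levels: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level as reference)."""
    k = len(levels)
    if k <= 1:
        return np.empty((len(codes), 0))
    out = np.zeros((len(codes), k - 1))
    for j in range(1, k):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on [1, X]."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def scheirer_ray_hare(
    sample: FactorialSample, ss_type: str = "II"
) -> SRHResult:
    """Scheirer-Ray-Hare rank test of two crossed factors and their interaction.

    The N observations are ranked jointly with tie averaging; factorial sums of
    squares are computed on the ranks (model-comparison Type II by default,
    which coincides with the textbook cell/margin formulas for balanced
    designs; ``ss_type="I"`` gives sequential A-then-B sums of squares).  Each
    H = SS_effect / (SS_total / (N - 1)) is referred to the chi-square upper
    tail at the effect's degrees of freedom.

    Degenerate input (all values tied) yields NaN statistics with p = 1 and a
    warning.  An empty cell of the full cross raises ``ValueError``.
    """
    if ss_type not in ("I", "II"):
        raise ValueError("ss_type must be 'I' or 'II'")
    v = sample.values
    n = len(v)
    lev_a, code_a = np.unique(sample.factor_a, return_inverse=True)
    lev_b, code_b = np.unique(sample.factor_b, return_inverse=True)
    a, b = len(lev_a), len(lev_b)
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)

    if a > 1 and b > 1:
        for i, la in enumerate(lev_a):
            for j, lb in enumerate(lev_b):
                if not np.any((code_a == i) & (code_b == j)):
                    raise ValueError(f"empty cell: ({la!r}, {lb!r})")

    r = rank_with_ties(v)
    ss_total = float(np.sum((r - r.mean()) ** 2))
    if ss_total == 0.0:
        warnings.warn("all values tied; H statistics undefined", stacklevel=2)
        nan = float("nan")
        return SRHResult(nan, nan, nan, df_a, df_b, df_ab,
                         1.0, 1.0, 1.0, nan, nan, nan, n)
    ms_total = ss_total / (n - 1)

    Xa = _dummy(lev_a, code_a)
    Xb = _dummy(lev_b, code_b)
    if df_ab > 0:
        Xab = np.einsum("ij,ik->ijk", Xa, Xb).reshape(n, df_a * df_b)
    else:
        Xab = np.empty((n, 0))

    rss_1 = _rss(r, np.empty((n, 0)))
    rss_a = _rss(r, Xa)
    rss_b = _rss(r, Xb)
    rss_ab_main = _rss(r, np.hstack([Xa, Xb]))
    rss_full = _rss(r, np.hstack([Xa, Xb, Xab]))

    if ss_type == "II":
        ss_a = max(rss_b - rss_ab_main, 0.0)
        ss_b = max(rss_a - rss_ab_main, 0.0)
    else:  # Type I, order A then B
        ss_a = max(rss_1 - rss_a, 0.0)
        ss_b = max(rss_a - rss_ab_main, 0.0)
    ss_ab = max(rss_ab_main - rss_full, 0.0)

    def _h_p(ss: float, df: int) -> tuple[float, float]:
        if df == 0:
            return 0.0, 1.0
        h = ss / ms_total
        return h, float(_sps.chi2.sf(h, df))

    H_a, p_a = _h_p(ss_a, df_a)
    H_b, p_b = _h_p(ss_b, df_b)
    H_ab, p_ab = _h_p(ss_ab, df_ab)

    def _eta2(h: float, k: int) -> float:
        if k < 2 or n <= k:
            return float("nan")
        return kruskal_eta_squared(h, k, n)[0]

    return SRHResult(
        H_a, H_b, H_ab, df_a, df_b, df_ab, p_a, p_b, p_ab,
        _eta2(H_a, a), _eta2(H_b, b), _eta2(H_ab, a * b), n,
    )


def kruskal_eta_squared(H: float, k: int, n: int) -> tuple[float, str]:
    """Eta-squared effect size from a Kruskal-Wallis-type H statistic.

    eta2 = (H - k + 1) / (n - k) for k groups and n observations; the label
    follows the conventional cut-offs (< 0.01 negligible, < 0.06 small,
    < 0.14 moderate, else large).
    """
    if k < 2:
        raise ValueError("need at least 2 groups")
    if n <= k:
        raise ValueError("need n > k observations")
    if H < 0:
        raise ValueError("H must be nonnegative")
    eta2 = (H - k + 1) / (n - k)
    return eta2, eta_squared_label(eta2)


def eta_squared_label(eta2: float) -> str:
    if math.isnan(eta2):
        return "undefined"
    if eta2 < 0.01:
        return "negligible"
    if eta2 < 0.06:
        return "small"
    if eta2 < 0.14:
        return "moderate"
    return "large"


@dataclass(frozen=True)
class DunnComparison:
    group_i: str
    group_j: str
    z: float
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class DunnResult:
    comparisons: list[DunnComparison] = field(default_factory=list)


def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    comparisons: Sequence[tuple[str, str]],
) -> DunnResult:
    """Dunn's post-hoc z-tests on mean joint ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum over tie groups of t^3 - t; two-sided normal p-values and
    Bonferroni adjustment over the requested comparison set.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g) or len(v) == 0:
        raise ValueError("values and groups must be equal-length and nonempty")
    r = rank_with_ties(v)
    N = len(v)
    tie = _tie_term(v)
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1)) if N > 1 else 0.0

    mean_rank: dict[str, float] = {}
    count: dict[str, int] = {}
    for lev in np.unique(g):
        mask = g == lev
        count[str(lev)] = int(mask.sum())
        mean_rank[str(lev)] = float(r[mask].mean())

    m = len(comparisons)
    out: list[DunnComparison] = []
    for gi, gj in comparisons:
        if gi not in mean_rank or gj not in mean_rank:
            raise ValueError(f"comparison references unknown group: ({gi}, {gj})")
        se = math.sqrt(var_base * (1.0 / count[gi] + 1.0 / count[gj]))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * float(_sps.norm.sf(abs(z)))
        out.append(DunnComparison(gi, gj, z, min(p, 1.0), min(1.0, m * min(p, 1.0))))
    return DunnResult(out)


def wilcoxon_ranksum_cc(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the joint ranking.
    The p-value uses the tie-corrected normal approximation with a 0.5
    continuity correction shrinking the statistic toward its null mean.
    Fully tied samples give p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n1, n2 = len(xa), len(ya)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    joint = np.concatenate([xa, ya])
    r = rank_with_ties(joint)
    W = float(r[:n1].sum())
    N = n1 + n2
    mean_W = n1 * (N + 1) / 2.0
    tie = _tie_term(joint)
    var_W = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var_W <= 0.0:
        return W, 1.0
    d = W - mean_W
    d_cc = math.copysign(max(abs(d) - 0.5, 0.0), d)
    z = d_cc / math.sqrt(var_W)
    p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
    return W, p


def two_proportion_z(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float, bool]:
    """Pooled two-proportion z-test.

    z = (x1/n1 - x2/n2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    p = (x1+x2)/(n1+n2); two-sided normal p-value.  Returns
    ``(z, p, degenerate)`` where ``degenerate`` flags a pooled proportion of
    exactly 0 or 1 (z reported as 0).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n with n > 0 for both samples")
    p_hat = (x1 + x2) / (n1 + n2)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0, True
    se = math.sqrt(p_hat * (1 - p_hat) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = min(1.0, 2.0 * float(_sps.norm.sf(abs(z))))
    return z, p, False
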