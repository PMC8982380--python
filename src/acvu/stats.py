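"""Nonparametric comparison statistics with exact small-sample modes.

Fluorescence comparisons between conditions use rank-based tests
throughout (per-nucleus integrated intensities are right-skewed and on an
arbitrary scale): two-sided Mann-Whitney U for two groups, Kruskal-Wallis
with Dunn's post-hoc comparisons against a control for several, Fisher's
exact test for 2x2 phenotype tables, and t-based 95% confidence intervals
on condition means for display.

For small samples the U and Kruskal-Wallis tests offer exact modes that
enumerate the full permutation distribution; two-sided exact p-values use
the standard doubling convention, 2 * min(lower tail, upper tail) capped
at 1.  Fisher's two-sided p follows the probability convention: the sum of
hypergeometric probabilities of tables no more probable than the observed
one.  All rank-based p-values are invariant under monotone transformations
of the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: tuple
    adjusted: bool = False
    mode: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts[counts > 1]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def exact_u_distribution(m: int, n: int) -> tuple:
    """Counts of the null distribution of U (index = U value, 0..m*n),
    by enumeration of all C(m+n, m) rank assignments."""
    counts = [0] * (m * n + 1)
    base = m * (m + 1) // 2
    for comb in itertools.combinations(range(1, m + n + 1), m):
        counts[sum(comb) - base] += 1
    return tuple(counts)


def _exact_u_p(u: float, m: int, n: int) -> float:
    counts = np.array(exact_u_distribution(m, n), dtype=float)
    total = counts.sum()
    ui = int(round(u))
    lower = counts[: ui + 1].sum() / total
    upper = counts[ui:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney_u(x, y, mode: str = "auto") -> StatResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates the permutation distribution of U (valid
    only without ties); ``'asymptotic'`` uses the normal approximation with
    tie correction and continuity correction; ``'auto'`` picks exact for
    n_x + n_y <= 12 tie-free data.
    The reported statistic is U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:m].sum() - m * (m + 1) / 2)
    has_ties = _tie_counts(pooled).size > 0

    if mode == "auto":
        mode = "exact" if (m + n <= 12 and not has_ties) else "asymptotic"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = _exact_u_p(u1, m, n)
    elif mode == "asymptotic":
        mu = m * n / 2.0
        ties = _tie_counts(pooled)
        N = m + n
        tie_term = ties.astype(float) ** 3 - ties if ties.size else np.array([0.0])
        var = m * n / 12.0 * ((N + 1) - tie_term.sum() / (N * (N - 1)))
        if var <= 0:  # all observations identical
            return StatResult("mann-whitney-u", u1, 1.0, (m, n), mode=mode)
        z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult("mann-whitney-u", u1, p, (m, n), mode=mode)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's post hoc
# ---------------------------------------------------------------------------


def _h_statistic(ranks_by_group, N: int, tie_corr: float) -> float:
    h = 12.0 / (N * (N + 1)) * sum(r.sum() ** 2 / r.size for r in ranks_by_group) - 3 * (N + 1)
    return h / tie_corr if tie_corr > 0 else 0.0


def kruskal_wallis(groups, mode: str = "auto", exact_max_n: int = 10) -> StatResult:
    """Kruskal-Wallis rank test across >= 2 groups.

    H uses the standard tie correction; the p-value comes from the
    chi-square reference with k-1 df, or from full enumeration of the
    group-label permutation distribution when the pooled sample is small
    (``mode='exact'``, default for total n <= ``exact_max_n``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = tuple(g.size for g in groups)
    N = sum(sizes)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    ties = _tie_counts(pooled)
    tie_corr = 1.0 - float((ties.astype(float) ** 3 - ties).sum()) / (N**3 - N) if ties.size else 1.0

    idx = np.cumsum((0,) + sizes)
    rank_groups = [ranks[idx[i] : idx[i + 1]] for i in range(len(sizes))]
    if tie_corr <= 0:  # every observation identical
        return StatResult("kruskal-wallis", 0.0, 1.0, sizes, mode="degenerate")
    h_obs = _h_statistic(rank_groups, N, tie_corr)

    if mode == "auto":
        mode = "exact" if N <= exact_max_n else "asymptotic"
    if mode == "asymptotic":
        p = float(sps.chi2.sf(h_obs, df=len(groups) - 1))
    elif mode == "exact":
        count = 0
        total = 0
        for perm_groups in _assignments(ranks, sizes):
            h = _h_statistic(perm_groups, N, tie_corr)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult("kruskal-wallis", h_obs, min(p, 1.0), sizes, mode=mode)


def _assignments(ranks, sizes):
    """Yield every way of assigning the pooled ranks to groups of the given
    sizes (index-set enumeration)."""
    indices = list(range(len(ranks)))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for comb in itertools.combinations(remaining, k):
            for rest in rec([i for i in remaining if i not in comb], sizes_left[1:]):
                yield [list(comb)] + rest

    for assign in rec(indices, list(sizes)):
        yield [ranks[g] for g in (np.array(a) for a in assign)]


def dunn_posthoc(groups, control: int = 0, adjustment: str = "bonferroni") -> list[StatResult]:
    """Dunn's multiple-comparison z tests of each group against a control.

    Pairwise z statistics on mean ranks from the pooled ranking with tie
    correction; two-sided normal p-values are adjusted over the comparison
    family (Bonferroni by default; ``adjustment=None`` for raw).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if not 0 <= control < len(groups):
        raise ValueError(f"control index {control} out of range")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    sizes = [g.size for g in groups]
    N = sum(sizes)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    ties = _tie_counts(pooled)
    tie_term = float((ties.astype(float) ** 3 - ties).sum()) / (12.0 * (N - 1)) if ties.size else 0.0
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(sizes))]

    m_comp = len(groups) - 1
    out = []
    for i in range(len(groups)):
        if i == control:
            continue
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[control])
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[control]) / math.sqrt(var)
            p_raw = 2.0 * float(sps.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p = min(1.0, m_comp * p_raw)
            adjusted = True
        elif adjustment is None:
            p, adjusted = min(1.0, p_raw), False
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        out.append(
            StatResult(
                "dunn",
                z,
                p,
                (sizes[i], sizes[control]),
                adjusted=adjusted,
                mode=f"vs-control[{control}]",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Conditional on the margins, the first cell follows a hypergeometric
    distribution; the two-sided p sums the probabilities of all tables as
    or less probable than the observed one (probability method).  The
    statistic reported is the sample odds ratio (inf when undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return StatResult("fisher-exact", 1.0, 1.0, (r1, r2))

    # integer hypergeometric weights make the "as or less probable" comparison
    # exact; float pmf comparisons can misorder theoretically tied tables
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    p = sum(w for w in weights if w <= w_obs) / math.comb(n, c1)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else 1.0
    if not math.isfinite(odds):
        odds = float(np.finfo(float).max)  # keep StatResult finite; p carries the inference
    return StatResult("fisher-exact", odds, min(p, 1.0), (r1, r2))


# ---------------------------------------------------------------------------
# confidence interval on a mean
# ---------------------------------------------------------------------------


def mean_ci95(values) -> tuple[float, float, float]:
    """t-based 95% confidence interval on the mean (small per-group n make
    the t reference the right default).  Returns (mean, lower, upper)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    m = float(v.mean())
    se = float(v.std(ddof=1)) / math.sqrt(v.size)
    half = float(sps.t.ppf(0.975, df=v.size - 1)) * se
    return m, m - half, m + half
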