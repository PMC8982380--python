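"""Rank tests against enumeration oracles and scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from acvu import stats


def _mwu_bruteforce_p(x, y):
    """Independent oracle: two-sided exact p by enumerating every labelling
    of the pooled sample."""
    pooled = np.concatenate([x, y])
    m = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), m):
        us.append(ranks[list(comb)].sum() - m * (m + 1) / 2)
    us = np.array(us)
    lower = np.mean(us <= u_obs + 1e-9)
    upper = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        r = stats.mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)  # 2 * 1/20 labelings

    def test_identical_samples_p_one(self):
        r = stats.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_exact_matches_bruteforce_and_scipy(self, rng):
        for _ in range(25):
            m, n = rng.integers(2, 7, size=2)
            x = rng.normal(size=m)
            y = rng.normal(0.8, size=n)
            r = stats.mann_whitney_u(x, y, mode="exact")
            assert r.p_value == pytest.approx(_mwu_bruteforce_p(x, y), abs=1e-12)
            sp = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert r.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_exact_and_asymptotic_close_at_n6(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=6)
            pe = stats.mann_whitney_u(x, y, mode="exact").p_value
            pa = stats.mann_whitney_u(x, y, mode="asymptotic").p_value
            assert abs(pe - pa) <= 0.02

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError, match="tie"):
            stats.mann_whitney_u([1, 1, 2], [2, 3, 4], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])

    @given(
        x=st.lists(st.integers(0, 50), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 50), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_monotone_transform(self, x, y):
        r1 = stats.mann_whitney_u(x, y)
        fx = [math.exp(v / 10.0) for v in x]
        fy = [math.exp(v / 10.0) for v in y]
        r2 = stats.mann_whitney_u(fx, fy)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.statistic == pytest.approx(r2.statistic)


def _kw_h(groups):
    """Independent H computation (tie-corrected) for the oracle."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (N * (N + 1)) * sum(
        ranks[idx[i] : idx[i + 1]].sum() ** 2 / len(g) for i, g in enumerate(groups)
    ) - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    corr = 1 - (t**3 - t).sum() / (N**3 - N)
    return h / corr


class TestKruskalWallis:
    def test_all_equal_h_zero_p_one(self):
        r = stats.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_asymptotic_matches_scipy(self, rng):
        groups = [rng.normal(size=12), rng.normal(0.5, size=10), rng.normal(1.0, size=11)]
        r = stats.kruskal_wallis(groups, mode="asymptotic")
        sp = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(sp.statistic)
        assert r.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_exact_three_by_three_matches_full_enumeration(self):
        groups = [[1.0, 5.0, 9.0], [2.0, 6.0, 7.0], [3.0, 4.0, 8.0]]
        r = stats.kruskal_wallis(groups, mode="exact")
        # independent oracle: enumerate all 9!/(3!3!3!) = 1680 assignments
        pooled = np.concatenate(groups)
        h_obs = _kw_h(groups)
        count = total = 0
        for c1 in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in c1]
            for c2 in itertools.combinations(rest, 3):
                c3 = [i for i in rest if i not in c2]
                gs = [pooled[list(c1)], pooled[list(c2)], pooled[c3]]
                total += 1
                if _kw_h(gs) >= h_obs - 1e-12:
                    count += 1
        assert total == 1680
        assert r.p_value == pytest.approx(count / total, abs=0.01)

    def test_two_groups_exact_matches_mwu_exact(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(1.0, size=4)
        pkw = stats.kruskal_wallis([x, y], mode="exact").p_value
        pmwu = stats.mann_whitney_u(x, y, mode="exact").p_value
        assert pkw == pytest.approx(pmwu, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_adjusted_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = stats.dunn_posthoc([g, list(g), list(g)], control=0)
        assert all(r.p_value == pytest.approx(1.0) for r in res)
        assert all(r.adjusted for r in res)

    def test_bonferroni_is_m_times_raw(self, rng):
        groups = [rng.normal(size=8), rng.normal(1.0, size=8), rng.normal(2.0, size=8)]
        raw = stats.dunn_posthoc(groups, control=0, adjustment=None)
        adj = stats.dunn_posthoc(groups, control=0, adjustment="bonferroni")
        m = len(groups) - 1
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, m * r.p_value))

    def test_single_comparison_adjusted_equals_raw(self, rng):
        groups = [rng.normal(size=8), rng.normal(1.0, size=8)]
        raw = stats.dunn_posthoc(groups, control=0, adjustment=None)[0]
        adj = stats.dunn_posthoc(groups, control=0, adjustment="bonferroni")[0]
        assert adj.p_value == pytest.approx(raw.p_value)

    def test_control_index_out_of_range(self):
        with pytest.raises(ValueError):
            stats.dunn_posthoc([[1.0], [2.0]], control=5)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert stats.fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_5(self):
        # 2 of the C(10,5)=252 equally-margined tables are as extreme
        assert stats.fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_diagonal_10(self):
        assert stats.fisher_exact_2x2([[10, 0], [0, 10]]).p_value == pytest.approx(
            2 / 184756
        )

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            mine = stats.fisher_exact_2x2(t).p_value
            assert mine == pytest.approx(sps.fisher_exact(t)[1], rel=1e-9)

    def test_invariant_under_transposition(self, rng):
        for _ in range(20):
            t = rng.integers(0, 15, size=(2, 2))
            assert stats.fisher_exact_2x2(t).p_value == pytest.approx(
                stats.fisher_exact_2x2(t.T).p_value, rel=1e-12
            )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[1, -1], [0, 2]])


class TestMeanCI:
    def test_zero_variance_collapses(self):
        assert stats.mean_ci95([3.0, 3.0, 3.0]) == (3.0, 3.0, 3.0)

    def test_symmetric_about_mean(self, rng):
        v = rng.normal(size=30)
        m, lo, hi = stats.mean_ci95(v)
        assert lo <= m <= hi
        assert (m - lo) == pytest.approx(hi - m)

    def test_large_sample_width_matches_asymptotics(self, rng):
        v = rng.standard_normal(10000)
        _, lo, hi = stats.mean_ci95(v)
        assert (hi - lo) == pytest.approx(2 * 1.96 / 100, rel=0.10)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            stats.mean_ci95([1.0])
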