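import itertools
import math

import numpy as np
import pytest
from scipy import stats

from suvarness.survival import contingency_test, km_curve, kruskal_wallis, logrank_test


class TestKmCurve:
    def test_two_events_product_limit(self):
        curve = km_curve([1, 2], [1, 1])
        assert list(curve["time"]) == [1, 2]
        assert list(curve["survival"]) == [0.5, 0.0]

    def test_all_censored_curve_is_flat_one(self):
        curve = km_curve([5, 10, 20], [0, 0, 0])
        assert curve.empty  # no event times -> S stays 1

    def test_tied_events_single_step(self):
        # d=2 of n=4 at t=3: S(3) = 1 - 2/4 = 0.5
        curve = km_curve([3, 3, 5, 9], [1, 1, 0, 0])
        assert curve.loc[0, "n_at_risk"] == 4
        assert curve.loc[0, "survival"] == 0.5

    def test_censoring_between_events(self):
        # hand enumeration: t=1 (d=1,n=4), censor at 2, t=3 (d=1,n=2)
        curve = km_curve([1, 2, 3, 4], [1, 0, 1, 0])
        assert np.allclose(curve["survival"], [3 / 4, 3 / 4 * 1 / 2])

    def test_all_events_no_ties_matches_one_minus_ecdf(self, rng):
        t = rng.permutation(np.arange(1.0, 11.0))
        curve = km_curve(t, np.ones(10))
        for _, row in curve.iterrows():
            ecdf = np.mean(t <= row["time"])
            assert row["survival"] == pytest.approx(1 - ecdf)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(20, 40)
        e = (rng.random(40) < 0.7).astype(int)
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.survival_function_at_times(row["time"]).iloc[0]), abs=1e-10
            )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_curve([], [])


def logrank_two_group_oracle(t1, e1, t2, e2):
    """Textbook two-group log-rank: O-E with hypergeometric variance."""
    times = sorted({t for t, e in zip(list(t1) + list(t2), list(e1) + list(e2)) if e == 1})
    u = v = 0.0
    for et in times:
        n1 = sum(1 for t in t1 if t >= et)
        n2 = sum(1 for t in t2 if t >= et)
        d1 = sum(1 for t, e in zip(t1, e1) if t == et and e == 1)
        d2 = sum(1 for t, e in zip(t2, e2) if t == et and e == 1)
        n, d = n1 + n2, d1 + d2
        u += d1 - n1 * d / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = u * u / v
    return chi2, stats.chi2.sf(chi2, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 1, 1])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_two_group_oracle(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(5, 15, size=2)
            t1 = np.round(rng.exponential(10, n1), 1)
            t2 = np.round(rng.exponential(20, n2), 1)
            e1 = (rng.random(n1) < 0.8).astype(int)
            e2 = (rng.random(n2) < 0.8).astype(int)
            if e1.sum() + e2.sum() == 0:
                continue
            res = logrank_test([(t1, e1), (t2, e2)])
            chi2, p = logrank_two_group_oracle(t1, e1, t2, e2)
            assert res.statistic == pytest.approx(chi2, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.8).astype(int)
        g = rng.integers(0, 3, 60)
        res = logrank_test([(t[g == k], e[g == k]) for k in range(3)])
        ll = multivariate_logrank_test(t, g, e)
        assert res.df == 2
        assert res.statistic == pytest.approx(ll.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ll.p_value, abs=1e-8)

    def test_strong_hazard_ratio_power(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            t1 = r.exponential(30, 50)
            t2 = r.exponential(10, 50)  # hazard ratio 3
            e1, e2 = np.ones(50), np.ones(50)
            res = logrank_test([(t1, e1), (t2, e2)])
            hits += res.p_value < 0.01
        assert hits >= 95

    def test_null_p_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            t = r.exponential(15, 40)
            e = (r.random(40) < 0.8).astype(int)
            half = 20
            if e[:half].sum() + e[half:].sum() == 0:
                continue
            ps.append(logrank_test([(t[:half], e[:half]), (t[half:], e[half:])]).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invariant_under_time_rescaling(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.8).astype(int)
        groups = [(t[:15], e[:15]), (t[15:], e[15:])]
        scaled = [(7.3 * tt, ee) for tt, ee in groups]
        assert logrank_test(groups).statistic == pytest.approx(
            logrank_test(scaled).statistic, abs=1e-12
        )

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [0, 0]), ([3, 4], [0, 0])])


def kw_oracle(groups):
    """Brute-force rank-sum H with tie correction, from first principles."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (sum(r) / len(g) - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    corr = 1 - sum(c**3 - c for c in ties.values()) / (n**3 - n)
    return h / corr


class TestKruskalWallis:
    def test_fully_separated_two_groups_maximal_h(self):
        res = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert res.statistic == pytest.approx(kw_oracle([[1, 2, 3], [10, 11, 12]]))
        # no arrangement of these 6 ranks into 3+3 beats full separation
        best = max(
            kw_oracle([list(c), [x for x in range(6) if x not in c]])
            for c in itertools.combinations(range(6), 3)
        )
        assert res.statistic == pytest.approx(best)

    def test_identical_groups_near_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_and_scipy_on_random_instances(self, rng):
        for _ in range(500):
            sizes = rng.integers(2, 8, size=int(rng.integers(2, 5)))
            groups = [list(np.round(rng.normal(0, 1, s), 1)) for s in sizes]
            if len({x for g in groups for x in g}) == 1:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(kw_oracle(groups), abs=1e-10)
            sp = stats.kruskal(*groups)
            assert res.statistic == pytest.approx(sp.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(sp.pvalue, abs=1e-10)

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[2, 2], [2, 2]])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestContingency:
    def test_perfect_association_exact_value(self):
        # ((5,0),(0,5)): only the two extreme tables are as unlikely;
        # p = 2 / C(10,5)
        res = contingency_test([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / math.comb(10, 5))
        assert res.p_value == pytest.approx(fisher_oracle(5, 0, 0, 5))

    def test_identical_rows_independent(self):
        assert contingency_test([[4, 6], [4, 6]]).p_value == pytest.approx(1.0)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            assert contingency_test(t).p_value == pytest.approx(
                contingency_test(t.T).p_value, abs=1e-12
            )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            if a + b == 0 or c + d == 0:
                continue
            res = contingency_test([[a, b], [c, d]])
            assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[1, -2], [0, 3]])
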