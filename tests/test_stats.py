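"""Statistical battery vs independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from prismadapt.stats import (
    bonferroni,
    correlate_with_mi,
    omnibus_group_test,
    paired_t_log,
    pairwise_ranksum,
    screened_pearson,
    signed_rank,
    variance_f_test,
)


def kruskal_oracle(groups):
    """H from explicit rank sums with tie correction."""
    pooled = np.concatenate(groups)
    ranks = sst.rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestOmnibus:
    def test_identical_groups_give_zero_h(self):
        res = omnibus_group_test({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_rank_sum_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        res = omnibus_group_test(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        res = omnibus_group_test(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_label_permutation_leaves_null_distribution_invariant(self):
        """Permuting pooled observations across groups leaves the H
        distribution unchanged (same multiset of H values over relabelings)."""
        rng = np.random.default_rng(1)
        pooled = rng.normal(0, 1, 9)
        hs = []
        for _ in range(50):
            rng.shuffle(pooled)
            g = [pooled[:3], pooled[3:6], pooled[6:]]
            hs.append(omnibus_group_test(g).statistic)
        # all permuted H values arise from the same pooled sample: the
        # mean is near its null expectation E[H] = k - 1
        assert np.mean(hs) == pytest.approx(2.0, abs=1.0)

    def test_eta_squared_formula(self):
        groups = [np.arange(10.0), np.arange(10.0) + 2, np.arange(10.0) + 4]
        res = omnibus_group_test(groups)
        h, k, n = res.statistic, 3, 30
        assert res.effect_size == pytest.approx((h - k + 1) / (n - k), abs=1e-12)
        res2 = omnibus_group_test(groups, effect="epsilon2")
        assert res2.effect_size == pytest.approx(h / (n - 1), abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            omnibus_group_test({"a": [1.0], "b": [1.0, 2.0]})


class TestPairwiseRanksum:
    def test_z_matches_hand_ranked_oracle(self):
        """{1,2,3} vs {4,5,6}: W1=6, mean=10.5, var=5.25."""
        res = pairwise_ranksum({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})[0]
        z_oracle = (6 - 10.5) / math.sqrt(5.25)
        assert res.statistic == pytest.approx(z_oracle, abs=1e-10)
        assert res.extra["method"] == "exact"
        # exact one-sided orientation: complete separation of n=3 vs 3
        assert res.p == pytest.approx(0.1, abs=1e-9)  # 2 * (1/20)

    def test_bonferroni_adjustment(self):
        groups = {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5], "c": [10.0, 11, 12, 13]}
        results = pairwise_ranksum(groups)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))
            assert r.p_adjusted >= r.p

    def test_tie_corrected_z(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 5.0, 6.0])
        res = pairwise_ranksum({"a": x, "b": y})[0]
        pooled = np.concatenate([x, y])
        ranks = sst.rankdata(pooled)
        w1 = ranks[:4].sum()
        n = 8
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts) / (n * (n - 1))
        var = 4 * 4 / 12 * ((n + 1) - tie)
        assert res.statistic == pytest.approx((w1 - 18.0) / math.sqrt(var), abs=1e-10)


class TestSignedRank:
    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_p_one_sided_all_negative(self):
        """{1..6} vs {2..7}: all differences -1, one-sided p = 1/64."""
        res = signed_rank(np.arange(1.0, 7), np.arange(2.0, 8), tail="less")
        assert res.extra["method"] == "exact"
        assert res.p == pytest.approx(1 / 64, abs=1e-12)
        assert res.statistic == 0.0  # no positive differences

    def test_exact_matches_enumeration_oracle(self):
        """p equals a from-scratch enumeration over all sign patterns."""
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, 8)
        res = signed_rank(d, tail="greater")
        ranks = sst.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count += w >= w_obs - 1e-9
        assert res.p == pytest.approx(count / 2**8, abs=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, 40)
        res = signed_rank(d)
        assert res.extra["method"] == "normal"
        ref = sst.wilcoxon(d, correction=True, method="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestVarianceF:
    def test_ratio_definition(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 20)
        y = rng.normal(0, 1, 20)
        x = (x - x.mean()) / x.std(ddof=1) * 2  # exact variance 4
        y = (y - y.mean()) / y.std(ddof=1)  # exact variance 1
        res = variance_f_test(x, y)
        assert res.statistic == pytest.approx(4.0, abs=1e-10)
        assert res.df == (19, 19)
        assert res.p == pytest.approx(2 * sst.f.sf(4.0, 19, 19), abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 2.0], [3.0, 3.0])


class TestPairedTLog:
    def test_matches_scipy_on_logs(self):
        rng = np.random.default_rng(3)
        pre = rng.lognormal(0.5, 0.4, 16)
        post = pre * rng.lognormal(0.3, 0.2, 16)
        res = paired_t_log(pre, post)
        ref = sst.ttest_rel(np.log10(post), np.log10(pre))
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.df == 15

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            paired_t_log([1.0, -1.0], [2.0, 3.0])


class TestScreenedPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = screened_pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.n_used == 10

    def test_outlier_excluded_and_reported(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 19)
        y = -x
        x = np.append(x, 40.0)  # ~10 SD outlier in x
        y = np.append(y, 40.0)
        res = screened_pearson(x, y, ids=[f"s{i}" for i in range(20)])
        assert res.excluded_ids == ("s19",)
        assert res.n_used == 19
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.r_unscreened > res.r  # outlier dragged r upward

    def test_hand_computed_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        res = screened_pearson(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        oracle = (cx * cy).sum() / math.sqrt((cx**2).sum() * (cy**2).sum())
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_infinite_limit_reproduces_unscreened(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        res = screened_pearson(x, y, sd_limit=float("inf"))
        assert res.r == res.r_unscreened
        assert res.n_used == 30


class TestMIJoin:
    def test_identical_scores_give_unit_correlation(self):
        metrics = pd.DataFrame({"participant_id": [f"p{i}" for i in range(14)],
                                "i_recal": np.linspace(0.1, 0.9, 14)})
        mi = metrics.rename(columns={"i_recal": "mi"})
        res = correlate_with_mi(metrics, mi)
        assert res.statistic == pytest.approx(1.0)
        assert res.n == 14

    def test_partial_join_reports_n_and_unmatched(self):
        metrics = pd.DataFrame({"participant_id": [f"p{i}" for i in range(20)],
                                "i_recal": np.linspace(0.1, 0.9, 20)})
        rng = np.random.default_rng(1)
        mi = pd.DataFrame({"participant_id": [f"p{i}" for i in range(14)],
                           "mi": rng.uniform(0, 1, 14)})
        res = correlate_with_mi(metrics, mi)
        assert res.n == 14
        assert res.extra["unmatched_metrics_ids"] == [f"p{i}" for i in range(14, 20)]

    def test_disjoint_ids_rejected(self):
        metrics = pd.DataFrame({"participant_id": ["a", "b", "c"], "i_recal": [0.1, 0.2, 0.3]})
        mi = pd.DataFrame({"participant_id": ["x", "y", "z"], "mi": [0.5, 0.6, 0.7]})
        with pytest.raises(ValueError, match="shared"):
            correlate_with_mi(metrics, mi)


def test_bonferroni_caps_and_is_monotone():
    assert bonferroni(0.5, 3) == 1.0
    assert bonferroni(0.01, 3) == pytest.approx(0.03)
    ps = np.linspace(0.001, 0.4, 20)
    adj = [bonferroni(p, 3) for p in ps]
    assert all(a2 >= a1 for a1, a2 in zip(adj, adj[1:]))
    assert max(adj) <= 1.0
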