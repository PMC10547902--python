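"""Statistical battery: tests against enumeration / closed-form oracles."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from cryscope import integrate_stats as ist

SEED = 31415


def _exact_mw_p(a, b):
    """Enumerate all rank arrangements for the exact two-sided U p value."""
    pooled = np.concatenate([a, b])
    n = len(a)
    idx = range(len(pooled))
    ranks = rankdata(pooled)

    def u_of(subset):
        r = sum(ranks[i] for i in subset)
        return r - n * (n + 1) / 2

    u_obs = u_of(range(n))
    m = len(pooled) - n
    mid = n * m / 2
    count = total = 0
    for subset in combinations(idx, n):
        u = u_of(subset)
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_exact_p_on_separated_triples(self):
        a, b = [1, 2, 3], [4, 5, 6]
        oracle = _exact_mw_p(np.array(a, float), np.array(b, float))
        assert oracle == pytest.approx(0.100)
        res = ist.mann_whitney(a, b)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_small_group_refused(self):
        with pytest.raises(ValueError):
            ist.mann_whitney([1.0], [2.0, 3.0])


class TestKruskalDunn:
    def test_identical_groups_nonsignificant(self):
        g = {"a": np.arange(10.0), "b": np.arange(10.0), "c": np.arange(10.0)}
        omni, posthoc = ist.kruskal_dunn(g)
        assert omni.p_value > 0.95
        assert all(r.p_adjusted > 0.9 for r in posthoc)
        assert len(posthoc) == 3

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(SEED)
        g = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
             "c": rng.normal(3, 1, 40)}
        omni, posthoc = ist.kruskal_dunn(g)
        assert omni.p_value < 1e-6
        by_pair = {r.extra["pair"]: r for r in posthoc}
        assert by_pair[("a", "c")].p_adjusted < 0.001
        assert by_pair[("a", "b")].p_adjusted > 0.05

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(SEED)
        g = {k: rng.normal(i * 0.5, 1, 25) for i, k in enumerate("abc")}
        _, posthoc = ist.kruskal_dunn(g)
        for r in posthoc:
            assert r.p_adjusted >= r.p_value - 1e-12


class TestAnovaTukeyBootstrap:
    def test_shifted_alternative_detected(self):
        rng = np.random.default_rng(SEED)
        detected = 0
        for rep in range(10):
            g = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                 "c": rng.normal(2.0, 1, 30)}
            _, posthoc = ist.anova_tukey_bootstrap(g, reps=1500, seed=rep)
            by_pair = {r.extra["pair"]: r for r in posthoc}
            if by_pair[("a", "c")].p_value < 0.05 and by_pair[("b", "c")].p_value < 0.05:
                detected += 1
        assert detected >= 9

    def test_null_mostly_nonsignificant(self):
        rng = np.random.default_rng(SEED)
        g = {k: rng.normal(0, 1, 30) for k in "abc"}
        _, posthoc = ist.anova_tukey_bootstrap(g, reps=1500, seed=0)
        assert all(r.p_value > 0.05 for r in posthoc)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(SEED)
        g = {k: rng.normal(0, 1, 20) for k in "abc"}
        _, p1 = ist.anova_tukey_bootstrap(g, reps=500, seed=5)
        _, p2 = ist.anova_tukey_bootstrap(g, reps=500, seed=5)
        assert [r.p_value for r in p1] == [r.p_value for r in p2]


class TestHolm:
    def test_hand_stepped_examples(self):
        assert ist.holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        assert ist.holm_bonferroni([0.03, 0.02]) == pytest.approx([0.04, 0.04])
        assert ist.holm_bonferroni([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_at_least_raw_and_order_invariant(self, ps):
        adj = ist.holm_bonferroni(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        perm = list(reversed(range(len(ps))))
        adj_perm = ist.holm_bonferroni([ps[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        table = pd.DataFrame({"x": x, "lin": 2 * x + 1, "neg": -x})
        rho, _ = ist.spearman_matrix(table)
        assert rho.loc["x", "lin"] == pytest.approx(1.0)
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(SEED)
        x, y = rng.normal(size=5), rng.normal(size=5)
        rho, _ = ist.spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        rx, ry = rankdata(x), rankdata(y)
        oracle = 1 - 6 * np.sum((rx - ry) ** 2) / (5 * (5**2 - 1))
        assert rho.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(SEED)
        table = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        rho, p = ist.spearman_matrix(table)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)
        assert np.allclose(np.diag(rho), 1.0)
        assert ((rho.to_numpy() >= -1) & (rho.to_numpy() <= 1)).all()

    def test_pairwise_complete_with_missing(self):
        table = pd.DataFrame({
            "x": [1.0, 2.0, 3.0, np.nan, 5.0],
            "y": [2.0, 4.0, 6.0, 8.0, 10.0],
        })
        rho, _ = ist.spearman_matrix(table)
        assert rho.loc["x", "y"] == pytest.approx(1.0)


def _w_oracle(arr):
    """Direct evaluation of the tie-corrected concordance formula."""
    ranks = np.vstack([rankdata(r) for r in arr])
    m, n = ranks.shape
    r_i = ranks.sum(axis=0)
    s = np.sum((r_i - r_i.mean()) ** 2)
    t = sum(np.sum(c**3 - c) for row in ranks
            for c in [np.unique(row, return_counts=True)[1]])
    return 12 * s / (m**2 * (n**3 - n) - m * t)


class TestKendallW:
    def test_identical_rankings(self):
        arr = np.tile(np.array([3.0, 1.0, 2.0, 4.0]), (3, 1))
        assert ist.kendall_w(arr) == pytest.approx(1.0)

    def test_reversed_pair(self):
        arr = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert ist.kendall_w(arr) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_with_ties(self):
        rng = np.random.default_rng(SEED)
        for _ in range(10):
            arr = rng.integers(0, 5, size=(3, 4)).astype(float)
            if np.any([len(np.unique(r)) == 1 for r in arr]):
                continue
            assert ist.kendall_w(arr) == pytest.approx(_w_oracle(arr), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        w1 = ist.kendall_w(np.vstack([x, y]))
        w2 = ist.kendall_w(np.vstack([np.exp(x), y**3]))
        assert w1 == pytest.approx(w2, abs=1e-12)
        assert 0.0 <= w1 <= 1.0


class TestBalancedSubsample:
    def test_sizes_and_determinism(self):
        rng = np.random.default_rng(SEED)
        g = {"a": rng.normal(size=300), "b": rng.normal(size=295)}
        out1 = ist.balanced_subsample(g, seed=3)
        out2 = ist.balanced_subsample(g, seed=3)
        assert {k: len(v) for k, v in out1.items()} == {"a": 295, "b": 295}
        np.testing.assert_array_equal(out1["a"], out2["a"])

    def test_equal_sizes_unchanged(self):
        g = {"a": np.arange(5.0), "b": np.arange(5.0) + 1}
        out = ist.balanced_subsample(g, seed=0)
        np.testing.assert_array_equal(out["a"], g["a"])


class TestConcordanceReport:
    def test_flag_thresholds(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        tables = {"cry": pd.DataFrame({"f0_mean": x, "eeg_delta": 2 * x})}
        rep = ist.concordance_report(tables, ["f0_mean"], ["eeg_delta"])
        row = rep.iloc[0]
        assert row["W"] == pytest.approx(1.0)
        assert row["strong"] and row["framed"]

    def test_null_features_rarely_framed(self):
        """Independent features almost never reach the W > 0.7 flag.

        For two rankers W = (rho_s + 1) / 2, so under independence W
        scatters symmetrically around 0.5; the very-strong 0.7 flag
        corresponds to rho_s > 0.4, a small-probability tail.
        """
        rng = np.random.default_rng(SEED)
        audio = [f"a{i}" for i in range(5)]
        partners = [f"p{i}" for i in range(6)]
        table = pd.DataFrame(rng.normal(size=(30, 11)), columns=audio + partners)
        rep = ist.concordance_report({"cry": table}, audio, partners)
        assert (~rep["framed"]).mean() >= 0.9
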