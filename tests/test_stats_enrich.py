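"""Statistical primitives: BH, hypergeometric ORA, rank-sum, paired t,
one-way ANOVA + Tukey."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coelomyx import stats_enrich


def bh_bruteforce(p):
    """Step-up definition with a cumulative minimum from the largest rank."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        out = stats_enrich.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats_enrich.benjamini_hochberg([0.3])[0] == 0.3

    def test_matches_brute_force_small_m(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(1, 13)
            p = rng.random(m)
            out = stats_enrich.benjamini_hochberg(p)
            assert np.allclose(out, bh_bruteforce(list(p)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(100)
        out = stats_enrich.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(out, ref)

    def test_nan_propagated_and_excluded_from_m(self):
        out = stats_enrich.benjamini_hochberg([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], stats_enrich.benjamini_hochberg([0.01, 0.02]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_never_decreases_and_idempotent_property(self, p):
        out = stats_enrich.benjamini_hochberg(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        again = stats_enrich.benjamini_hochberg(out)
        order = np.argsort(p, kind="stable")
        # adjusted values are monotone in raw-p rank
        assert np.all(np.diff(out[order]) >= -1e-15)
        assert np.all(again <= 1.0)


def ora_enumeration(M, n, N, k):
    """Exact upper-tail overlap probability by enumerating all draws."""
    universe = range(M)
    inset = set(range(n))
    total = math.comb(M, N)
    hits = sum(1 for q in itertools.combinations(universe, N) if len(inset & set(q)) >= k)
    return hits / total


class TestHypergeometricORA:
    def _collection(self, M, sets):
        universe = {f"g{i}" for i in range(M)}
        return stats_enrich.GeneSetCollection(
            sets={name: {f"g{i}" for i in idx} for name, idx in sets.items()},
            universe=universe,
        )

    def test_full_overlap_exact_probability(self):
        col = self._collection(10, {"s": range(5)})
        table = stats_enrich.hypergeometric_ora({f"g{i}" for i in range(5)}, col)
        assert table["p"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_overlap_is_p_one(self):
        col = self._collection(10, {"s": range(3)})
        table = stats_enrich.hypergeometric_ora({"g8", "g9"}, col)
        assert table["p"].iloc[0] == 1.0

    def test_matches_enumeration_on_tiny_universes(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            M = int(rng.integers(5, 13))
            n = int(rng.integers(1, M))
            N = int(rng.integers(1, M))
            col = self._collection(M, {"s": range(n)})
            query = {f"g{i}" for i in rng.choice(M, size=N, replace=False)}
            k = len(query & col.sets["s"])
            p = stats_enrich.hypergeometric_ora(query, col)["p"].iloc[0]
            assert p == pytest.approx(ora_enumeration(M, n, N, k))

    def test_p_monotone_decreasing_in_overlap(self):
        M, n, N = 50, 10, 10
        ps = [float(stats.hypergeom.sf(k - 1, M, n, N)) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_query_empty_table(self):
        col = self._collection(10, {"s": range(3)})
        assert stats_enrich.hypergeometric_ora(set(), col).empty

    def test_empty_set_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            col = stats_enrich.GeneSetCollection(
                sets={"s": {"x"}}, universe={"g1", "g2"}
            )
        assert not col.sets

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        col = stats_enrich.GeneSetCollection.from_gmt(path)
        assert col.sets == {"setA": {"g1", "g2"}, "setB": {"g3"}}


class TestWilcoxonRankSum:
    def test_exact_separated_triples(self):
        out = stats_enrich.wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_groups_p_one(self):
        out = stats_enrich.wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert out["p"] == 1.0

    def test_tied_data_uses_midrank_approximation(self):
        out = stats_enrich.wilcoxon_rank_sum([1, 2, 2, 3], [2, 3, 3, 4])
        assert out["method"] == "asymptotic"
        assert 0 < out["p"] <= 1

    def test_large_sample_type_i_error(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            stats_enrich.wilcoxon_rank_sum(rng.standard_normal(30), rng.standard_normal(30))["p"] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08


class TestPairedT:
    def test_direction_check(self):
        rng = np.random.default_rng(4)
        b = rng.standard_normal(10) * 0.01
        a = b + 1.0
        assert stats_enrich.paired_t_one_tailed(a, b, "greater")["p"] < 1e-6
        assert stats_enrich.paired_t_one_tailed(a, b, "less")["p"] > 0.999

    def test_symmetric_differences_near_half(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a + np.array([1, -1, 1, -1, 1, -1]) * 0.5
        assert stats_enrich.paired_t_one_tailed(a, b, "greater")["p"] == pytest.approx(0.5, abs=0.05)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = stats.t.sf(t_ref, df=len(d) - 1)
        out = stats_enrich.paired_t_one_tailed(a, b, "greater")
        assert out["t"] == pytest.approx(t_ref)
        assert out["p"] == pytest.approx(p_ref)

    def test_zero_variance_flagged(self):
        out = stats_enrich.paired_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert out["degenerate"] and out["p"] == 1.0


class TestOnewayAnovaTukey:
    def test_identical_groups(self):
        out = stats_enrich.oneway_anova_tukey({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert out["F"] == 0.0 and out["p"] == 1.0
        assert (out["tukey"] == 1.0).all()

    def test_matches_hand_ss_decomposition(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        F_ref = (ss_between / 2) / (ss_within / 6)
        out = stats_enrich.oneway_anova_tukey(groups)
        assert out["F"] == pytest.approx(F_ref)

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(10), rng.standard_normal(10) + 1
        out = stats_enrich.oneway_anova_tukey({"a": a, "b": b})
        p_t = stats.ttest_ind(a, b).pvalue
        assert out["tukey"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            stats_enrich.oneway_anova_tukey({"a": [1], "b": [1, 2]})

    def test_invariant_to_group_order(self):
        groups = {"a": [1.0, 2.0], "b": [4.0, 5.0], "c": [2.0, 2.5]}
        out1 = stats_enrich.oneway_anova_tukey(groups)
        out2 = stats_enrich.oneway_anova_tukey(dict(reversed(groups.items())))
        assert out1["F"] == pytest.approx(out2["F"])
        assert out1["p"] == pytest.approx(out2["p"])
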