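"""Replicate agreement, cross-bait enrichment, Venn partitions, term enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mythscreen.compare import (
    bait_enrichment,
    cluster_rows,
    hit_set,
    replicate_agreement,
    term_enrichment,
    venn_counts,
)


def _table(bait, universe, hits, densities=None):
    densities = densities or {}
    return pd.DataFrame(
        {
            "bait": bait,
            "prey": list(universe),
            "mean_density": [densities.get(p, 100.0 if p in hits else 0.0) for p in universe],
            "positive": [p in hits for p in universe],
            "status": "ok",
        }
    )


class TestReplicateAgreement:
    def test_shared_fraction_of_published_counts(self):
        """Intersection 241 over union 372 gives 64.8%, printed as 65%."""
        universe = [f"p{i}" for i in range(400)]
        hits_a = set(universe[:300])                      # 241 shared + 59 unique to A
        hits_b = set(universe[:241]) | set(universe[300:372])
        res = replicate_agreement(_table("c", universe, hits_a), _table("c", universe, hits_b))
        assert res["shared"] == 241
        assert res["union"] == 372
        assert res["percent_shared"] == pytest.approx(100 * 241 / 372)
        assert round(res["percent_shared"]) == 65

    def test_identical_replicates(self):
        universe = [f"p{i}" for i in range(20)]
        dens = {p: float(i + 1) for i, p in enumerate(universe)}
        t = _table("c", universe, set(universe[:8]), dens)
        res = replicate_agreement(t, t.copy())
        assert res["percent_shared"] == 100.0
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_pearson_scale_invariance(self):
        universe = ["a", "b", "c", "d"]
        hits = {"a", "b", "c"}
        t1 = _table("x", universe, hits, {"a": 1.0, "b": 2.0, "c": 3.0})
        t2 = _table("x", universe, hits, {"a": 2.0, "b": 4.0, "c": 6.0})
        assert replicate_agreement(t1, t2)["pearson_r"] == pytest.approx(1.0)

    def test_mismatched_universe_rejected(self):
        t1 = _table("x", ["a", "b"], {"a"})
        t2 = _table("x", ["a", "c"], {"a"})
        with pytest.raises(ValueError, match="universes"):
            replicate_agreement(t1, t2)


class TestBaitEnrichment:
    def _tables(self, dens_by_bait, hits_by_bait, universe):
        return [
            _table(b, universe, hits_by_bait[b], dens_by_bait[b]) for b in dens_by_bait
        ]

    def test_twofold_dominance(self):
        universe = ["p"]
        tabs = self._tables(
            {"b1": {"p": 10.0}, "b2": {"p": 4.0}, "b3": {"p": 5.0}},
            {"b1": {"p"}, "b2": {"p"}, "b3": {"p"}},
            universe,
        )
        out = bait_enrichment(tabs)
        assert out == {"b1": {"p"}, "b2": set(), "b3": set()}

    def test_zero_elsewhere_counts_as_enriched(self):
        universe = ["p"]
        tabs = self._tables(
            {"b1": {"p": 10.0}, "b2": {"p": 0.0}, "b3": {"p": 0.0}},
            {"b1": {"p"}, "b2": set(), "b3": set()},
            universe,
        )
        assert bait_enrichment(tabs)["b1"] == {"p"}

    def test_below_twofold_not_enriched(self):
        universe = ["p"]
        tabs = self._tables(
            {"b1": {"p": 10.0}, "b2": {"p": 6.0}, "b3": {"p": 4.0}},
            {"b1": {"p"}, "b2": {"p"}, "b3": {"p"}},
            universe,
        )
        assert bait_enrichment(tabs) == {"b1": set(), "b2": set(), "b3": set()}

    def test_enriched_sets_disjoint_for_positive_densities(self):
        """Mutual 2× dominance is impossible when all densities are positive."""
        rng = np.random.default_rng(8)
        universe = [f"p{i}" for i in range(40)]
        tabs = []
        for b in ("b1", "b2", "b3"):
            dens = {p: float(rng.uniform(1, 100)) for p in universe}
            tabs.append(_table(b, universe, set(universe), dens))
        out = bait_enrichment(tabs)
        for x, y in combinations(out, 2):
            assert not (out[x] & out[y])

    def test_fold_must_exceed_one(self):
        universe = ["p"]
        tabs = self._tables(
            {"b1": {"p": 1.0}, "b2": {"p": 1.0}}, {"b1": {"p"}, "b2": {"p"}}, universe
        )
        with pytest.raises(ValueError):
            bait_enrichment(tabs, fold=1.0)


class TestVennCounts:
    def test_small_example(self):
        counts = venn_counts({"x": {"a", "b"}, "y": {"b", "c"}, "z": {"b"}})
        assert counts[frozenset({"x", "y", "z"})] == 1   # {b}
        assert counts[frozenset({"x"})] == 1             # {a}
        assert counts[frozenset({"y"})] == 1             # {c}
        assert counts[frozenset({"x", "y"})] == 0

    def test_disjoint_sets(self):
        counts = venn_counts({"x": {"a"}, "y": {"b"}})
        assert counts[frozenset({"x", "y"})] == 0
        assert counts[frozenset({"x"})] == 1

    def test_identical_sets(self):
        s = {"a", "b", "c", "d", "e"}
        counts = venn_counts({"x": s, "y": s, "z": s})
        assert counts[frozenset({"x", "y", "z"})] == 5
        assert sum(v for k, v in counts.items() if k != frozenset({"x", "y", "z"})) == 0

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.sets(st.integers(0, 20), max_size=10), min_size=2, max_size=4
        )
    )
    def test_region_counts_conserve_set_sizes(self, sets):
        named = {f"s{i}": s for i, s in enumerate(sets)}
        counts = venn_counts(named)
        assert sum(counts.values()) == len(set.union(set(), *sets))
        for name, s in named.items():
            incident = sum(v for k, v in counts.items() if name in k)
            assert incident == len(s)


def brute_force_upper_tail(N, K, n, k):
    """P(X ≥ k) by enumerating annotated-count outcomes of all n-subsets."""
    total = comb(N, n)
    favorable = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return favorable / total


class TestTermEnrichment:
    def test_worked_example(self):
        """Background 10, term annotates 5, all 4 hits annotated: p = 5/210."""
        background = [f"g{i}" for i in range(10)]
        annot = {g: ["T"] for g in background[:5]}
        hits = background[:4]
        res = term_enrichment(hits, annot, background).iloc[0]
        assert res["p_raw"] == pytest.approx(5 / 210)

    @pytest.mark.parametrize("N,K,n,k_annot", [(8, 3, 4, 3), (10, 5, 4, 2), (12, 6, 5, 4), (7, 2, 3, 1)])
    def test_matches_subset_enumeration(self, N, K, n, k_annot):
        background = [f"g{i}" for i in range(N)]
        annot = {g: ["T"] for g in background[:K]}
        hits = background[:k_annot] + background[K : K + (n - k_annot)]
        res = term_enrichment(hits, annot, background)
        expected = brute_force_upper_tail(N, K, n, k_annot)
        assert res.loc[res["term"] == "T", "p_raw"].iloc[0] == pytest.approx(expected)

    def test_hits_equal_background_gives_p_one(self):
        background = [f"g{i}" for i in range(6)]
        annot = {g: ["T"] for g in background[:3]}
        res = term_enrichment(background, annot, background)
        assert (res["p_raw"] == 1.0).all()

    def test_hitless_terms_excluded_from_bonferroni(self):
        background = [f"g{i}" for i in range(10)]
        annot = {background[0]: ["hit_term"], background[9]: ["other_term"]}
        res = term_enrichment(background[:3], annot, background).set_index("term")
        assert res.loc["other_term", "p_raw"] == 1.0
        # only one term annotates a hit, so no multiplicity inflation
        assert res.loc["hit_term", "p_adj"] == pytest.approx(res.loc["hit_term", "p_raw"])

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            term_enrichment(["x"], {}, ["a", "b"])


class TestClusterRows:
    def test_closest_rows_merge_first(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.1], [10.0, 10.0]], index=["r1", "r2", "r3"])
        order, merges = cluster_rows(m)
        assert set(merges[0, :2].astype(int)) == {0, 1}
        assert order.index("r3") in (0, 2)  # outlier at one end of the leaf order

    def test_identical_rows_merge_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2.0]] * 3)
        _, merges = cluster_rows(m)
        assert np.allclose(merges[:, 2], 0.0)

    def test_single_row_identity(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        order, merges = cluster_rows(m)
        assert order == ["only"]
        assert merges is None
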