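"""Hypergeometric co-association, BH correction, clustering, overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from translatomics.enrichment import (
    bh_adjust,
    cluster_matrix,
    coassociation_matrix,
    enrichment_heatmap_matrix,
    hypergeometric_lower,
    hypergeometric_upper,
    overlap_counts,
    term_enrichment,
)
from translatomics.io import GeneSetCollection


class TestHypergeometric:
    def test_zero_overlap_full_tail(self):
        assert hypergeometric_upper(0, 5, 4, 10) == 1.0

    def test_exact_combinatorial_example(self):
        # C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeometric_upper(4, 5, 4, 10) == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_matches_exhaustive_enumeration(self):
        """Upper tail equals brute-force enumeration over all C(N, n) draws
        for every configuration with N <= 12 (tolerance 1e-12)."""
        for N in range(1, 13):
            for K in range(N + 1):
                a_mask = (1 << K) - 1
                for n in range(N + 1):
                    tallies = [0] * (min(K, n) + 1)
                    for comb in itertools.combinations(range(N), n):
                        mask = 0
                        for i in comb:
                            mask |= 1 << i
                        tallies[bin(mask & a_mask).count("1")] += 1
                    total = math.comb(N, n)
                    for k in range(min(K, n) + 1):
                        expected = sum(tallies[k:]) / total
                        assert hypergeometric_upper(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_lower_plus_upper_consistency(self):
        # P(X<=k) + P(X>=k+1) = 1
        p = hypergeometric_lower(2, 6, 5, 15) + hypergeometric_upper(3, 6, 5, 15)
        assert p == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("args", [(5, 4, 4, 10), (1, 11, 4, 10), (-1, 5, 4, 10)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeometric_upper(*args)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_step_up_hand_calculation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_known_mixed_vector(self):
        # ranks: 0.005*4/1=0.02; 0.04*4/2=0.08 vs min(0.1)->0.08;
        # 0.03*4/3=0.0667 -> min with later 0.08? step-up: q3=min(0.08, 0.04)
        q = bh_adjust([0.005, 0.04, 0.03, 0.08])
        assert q == pytest.approx([0.02, 0.0533333333, 0.0533333333, 0.08])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_dominates_p(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 100) ** 3
        q = bh_adjust(p)
        alpha = 0.05
        bonf = p <= alpha / len(p)
        assert np.all(q[bonf] <= alpha + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCoassociation:
    def _collections(self):
        universe = frozenset(f"g{i}" for i in range(100))
        a = GeneSetCollection(
            {"A": frozenset(f"g{i}" for i in range(10))}, universe
        )
        b = GeneSetCollection(
            {"B": frozenset(f"g{i}" for i in range(10))}, universe
        )
        return a, b, universe

    def test_self_overlap_extreme(self):
        a, b, universe = self._collections()
        df = coassociation_matrix(a, b, universe)
        row = df.iloc[0]
        assert row["k"] == 10
        assert row["p"] < 1e-10
        assert row["direction"] == "over"

    def test_disjoint_sets_under_represented(self):
        universe = frozenset(f"g{i}" for i in range(40))
        a = GeneSetCollection({"A": frozenset(f"g{i}" for i in range(20))}, universe)
        b = GeneSetCollection(
            {"B": frozenset(f"g{i}" for i in range(20, 40))}, universe
        )
        row = coassociation_matrix(a, b, universe).iloc[0]
        assert row["k"] == 0
        assert row["direction"] == "under"
        assert row["p"] < 0.01

    def test_bh_applied_across_all_cells(self):
        universe = frozenset(f"g{i}" for i in range(60))
        rng = np.random.default_rng(2)
        a = GeneSetCollection(
            {f"A{i}": frozenset(rng.choice(sorted(universe), 10, replace=False))
             for i in range(4)}, universe,
        )
        b = GeneSetCollection(
            {f"B{i}": frozenset(rng.choice(sorted(universe), 10, replace=False))
             for i in range(3)}, universe,
        )
        df = coassociation_matrix(a, b, universe)
        assert len(df) == 12
        assert np.all(df["q"] >= df["p"] - 1e-15)

    def test_planted_target_set_recovered(self, small_dataset):
        """The Puf3-like target set (70% regulon overlap) co-associates
        with the down class at q < 0.01."""
        from translatomics.expression import TranslationStateCaller

        caller = TranslationStateCaller().fit(small_dataset.expression)
        calls = caller.calls_
        classes = GeneSetCollection(
            {
                lab: frozenset(calls.index[calls["label"] == lab])
                for lab in ("up", "down")
            },
            frozenset(calls.index),
        )
        df = coassociation_matrix(
            small_dataset.targets, classes, frozenset(calls.index)
        )
        row = df[(df.set_a == "Puf3_like") & (df.set_b == "down")].iloc[0]
        assert row["direction"] == "over"
        assert row["q"] < 0.01

    def test_empty_universe_errors(self):
        a = GeneSetCollection({"A": frozenset()})
        with pytest.raises(ValueError, match="universe"):
            coassociation_matrix(a, a, frozenset())


class TestTermEnrichment:
    def test_exact_term_ranks_first(self):
        universe = [f"g{i}" for i in range(50)]
        ann = GeneSetCollection(
            {
                "t1": frozenset(universe[:10]),
                "t2": frozenset(universe[20:40]),
            },
            frozenset(universe),
        )
        df = term_enrichment(universe[:10], ann, universe)
        assert df.iloc[0]["set_a"] == "t1"
        assert df.iloc[0]["k"] == 10

    def test_k_is_direct_intersection(self):
        universe = [f"g{i}" for i in range(30)]
        ann = GeneSetCollection({"t": frozenset(universe[:15])}, frozenset(universe))
        query = universe[10:20]
        df = term_enrichment(query, ann, universe)
        assert df.iloc[0]["k"] == len(set(query) & ann["t"])

    def test_random_queries_rarely_significant(self):
        """Random queries of matched size give min q > 0.05 in >= 90% of
        draws."""
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(300)]
        ann = GeneSetCollection(
            {f"t{j}": frozenset(rng.choice(universe, 30, replace=False))
             for j in range(10)},
            frozenset(universe),
        )
        ok = 0
        n_draws = 50
        for _ in range(n_draws):
            query = rng.choice(universe, 30, replace=False)
            df = term_enrichment(query, ann, universe)
            ok += df["q"].min() > 0.05
        assert ok / n_draws >= 0.90

    def test_query_outside_universe_dropped(self):
        universe = ["g1", "g2", "g3"]
        ann = GeneSetCollection({"t": frozenset(["g1"])}, frozenset(universe))
        df = term_enrichment(["g1", "gX"], ann, universe)
        assert df.iloc[0]["n"] == 1  # gX dropped from the query


class TestClustering:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]],
                         index=["a", "b", "c"])
        out = cluster_matrix(m)
        link = out["row_linkage"]
        assert link[0][2] == pytest.approx(0.0)  # first merge at distance 0
        assert {int(link[0][0]), int(link[0][1])} == {0, 1}

    def test_hand_traced_upgma_on_line(self):
        # points 0, 1, 10: {0,1} merge at 1, then average distance 9.5
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        link = cluster_matrix(m)["row_linkage"]
        assert link[0][2] == pytest.approx(1.0)
        assert link[1][2] == pytest.approx(9.5)

    def test_permutation_preserves_merge_heights(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"r{i}" for i in range(6)])
        h1 = sorted(cluster_matrix(m)["row_linkage"][:, 2])
        perm = m.iloc[[3, 1, 5, 0, 4, 2]]
        h2 = sorted(cluster_matrix(perm)["row_linkage"][:, 2])
        assert np.allclose(h1, h2)

    def test_single_row_identity(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["a"])
        out = cluster_matrix(m)
        assert out["row_order"] == ["a"]
        assert out["row_linkage"] is None

    def test_heatmap_matrix_signs(self):
        df = pd.DataFrame(
            {
                "set_a": ["A", "A"],
                "set_b": ["B", "C"],
                "q": [1e-4, 1e-3],
                "direction": ["over", "under"],
            }
        )
        m = enrichment_heatmap_matrix(df)
        assert m.loc["A", "B"] == pytest.approx(4.0)
        assert m.loc["A", "C"] == pytest.approx(-3.0)


class TestOverlapCounts:
    def test_disjoint_sets(self):
        coll = GeneSetCollection(
            {"A": frozenset("abc"), "B": frozenset("defg")}
        )
        counts = overlap_counts(coll)
        assert counts["10"] == 3
        assert counts["01"] == 4
        assert counts["11"] == 0

    def test_identical_sets(self):
        coll = GeneSetCollection(
            {"A": frozenset("abc"), "B": frozenset("abc")}
        )
        counts = overlap_counts(coll)
        assert counts == {"11": 3, "10": 0, "01": 0}

    def test_counts_match_per_gene_tabulation(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        sets = {
            name: frozenset(rng.choice(genes, rng.integers(5, 30), replace=False))
            for name in "ABC"
        }
        coll = GeneSetCollection(dict(sets))
        counts = overlap_counts(coll)
        union = sets["A"] | sets["B"] | sets["C"]
        assert sum(counts.values()) == len(union)
        for gene in union:
            key = "".join("1" if gene in sets[n] else "0" for n in "ABC")
            assert counts[key] >= 1

    def test_more_than_six_sets_rejected(self):
        coll = GeneSetCollection(
            {f"S{i}": frozenset(["g1"]) for i in range(7)}
        )
        with pytest.raises(ValueError, match="6"):
            overlap_counts(coll)
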