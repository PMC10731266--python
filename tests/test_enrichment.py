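"""Hypergeometric overrepresentation (vs. enumeration), BH, Z-scores, rankings."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from somportrait.enrichment import (
    GeneSet,
    enrich_all,
    gene_set_zscore,
    overrepresentation,
    read_gmt,
    setcount_per_spot,
    top_genes,
    top_sets_per_spot,
    write_gmt_sets,
    zscore_table,
)
from somportrait.portraits import SpotModule
from somportrait.preprocess import ExpressionMatrix


def make_spot(label: str, genes: list[str]) -> SpotModule:
    return SpotModule(label, frozenset({(0, 0)}), 1.0, (0, 0), "warm", tuple(genes))


def exact_tail(k: int, N: int, K: int, n: int) -> float:
    """Closed-form hypergeometric upper tail via exact integer arithmetic."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestOverrepresentation:
    def test_example_matches_enumeration_over_all_draws(self):
        """N=20, K=5, n=4, k=3: enumerate all C(20,4) draws explicitly."""
        universe = [f"g{i}" for i in range(20)]
        members = frozenset(universe[:5])
        spot = universe[:3] + [universe[10]]  # overlap 3
        res = overrepresentation(spot, GeneSet("s", members), universe)
        assert res.k == 3
        hits = sum(
            1
            for draw in itertools.combinations(universe, 4)
            if len(members & set(draw)) >= 3
        )
        assert res.p_value == pytest.approx(hits / comb(20, 4), rel=1e-12)

    def test_tail_equals_exact_enumeration_for_all_small_universes(self):
        """Full sweep N ≤ 25: scipy tail must equal integer-exact arithmetic."""
        from scipy import stats

        rng = np.random.default_rng(0)
        for N in range(2, 26):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(1, N + 1, max(1, N // 4)):
                    ks = np.arange(0, min(K, n) + 1)
                    p = stats.hypergeom.sf(ks - 1, N, K, n)
                    expected = [exact_tail(int(k), N, K, n) for k in ks]
                    assert np.allclose(p, expected, rtol=1e-10)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = overrepresentation(universe[:3], GeneSet("s", frozenset(universe[5:])), universe)
        assert res.k == 0
        assert res.p_value == pytest.approx(1.0)

    def test_set_equal_to_universe_saturates(self):
        universe = [f"g{i}" for i in range(10)]
        res = overrepresentation(universe[:4], GeneSet("all", frozenset(universe)), universe)
        assert res.k == res.n == 4
        assert res.p_value == pytest.approx(1.0)

    def test_errors(self):
        universe = ["a", "b"]
        with pytest.raises(ValueError):
            overrepresentation([], GeneSet("s", frozenset("a")), universe)
        with pytest.raises(ValueError):
            overrepresentation(["a"], GeneSet("s", frozenset("a")), [])
        with pytest.raises(ValueError, match="outside"):
            overrepresentation(["zzz"], GeneSet("s", frozenset("a")), universe)


class TestEnrichAll:
    def test_bh_adjustment_invariants(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(200)]
        spots = [
            make_spot(label, list(rng.choice(universe, 30, replace=False)))
            for label in "ABC"
        ]
        sets = [
            GeneSet(f"set{i}", frozenset(rng.choice(universe, 25, replace=False)))
            for i in range(10)
        ]
        table = enrich_all(spots, sets, universe)
        assert len(table) == 30
        assert (table["adj_p"] >= table["p_value"] - 1e-15).all()
        assert (table["adj_p"] <= 1.0).all()
        ordered = table.sort_values("p_value")
        assert ordered["adj_p"].is_monotonic_increasing

    def test_null_sets_type_one_error_calibration(self):
        """Raw p < 0.05 for ≈5% of 1,000 random sets with no planted structure."""
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(2000)]
        spot_genes = list(rng.choice(universe, 400, replace=False))
        spot = make_spot("S", spot_genes)
        sets = [
            GeneSet(f"null{i}", frozenset(rng.choice(universe, 40, replace=False)))
            for i in range(1000)
        ]
        table = enrich_all([spot], sets, universe)
        fraction = (table["p_value"] < 0.05).mean()
        assert abs(fraction - 0.05) < 0.025

    def test_top_sets_view(self):
        universe = [f"g{i}" for i in range(50)]
        spot = make_spot("A", universe[:10])
        sets = [GeneSet(f"s{i}", frozenset(universe[i : i + 10])) for i in range(5)]
        table = enrich_all([spot], sets, universe)
        top = top_sets_per_spot(table, k=2)
        assert len(top) == 2
        assert top.loc[0, "set"] == "s0"  # the fully-overlapping set ranks first


class TestZScores:
    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(50, 6))
        values -= values.mean(axis=1, keepdims=True)
        return ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(50)]),
            scale="log10-qnorm-centered",
        )

    def test_whole_universe_set_scores_zero(self, matrix):
        z = gene_set_zscore(matrix, GeneSet("all", frozenset(matrix.gene_ids)))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_matches_brute_force_recomputation(self, matrix):
        members = [f"g{i}" for i in range(0, 20, 3)]
        z = gene_set_zscore(matrix, GeneSet("s", frozenset(members)))
        values = matrix.values
        for j, sample in enumerate(matrix.sample_ids):
            rows = [int(g[1:]) for g in members]
            expected = (values[rows, j].mean() - values[:, j].mean()) / (
                values[:, j].std(ddof=1) / np.sqrt(len(members))
            )
            assert z[sample] == pytest.approx(expected)

    def test_singleton_gene_at_sample_mean_scores_zero(self):
        values = np.array([[1.0, -1.0], [0.0, 0.0], [-1.0, 1.0]])
        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=["a", "mid", "b"]), scale="log10-qnorm-centered"
        )
        z = gene_set_zscore(matrix, GeneSet("solo", frozenset({"mid"})))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_constant_shift_of_a_column_leaves_its_z_unchanged(self, matrix):
        """Location contract: shift one sample, re-centralize, z is unchanged."""
        members = frozenset([f"g{i}" for i in range(10)])
        z_before = gene_set_zscore(matrix, GeneSet("s", members))
        shifted = matrix.df.copy()
        shifted.iloc[:, 2] += 5.0
        recentered = shifted - shifted.mean(axis=1).to_numpy()[:, None]
        matrix2 = ExpressionMatrix(recentered, scale="log10-qnorm-centered")
        z_after = gene_set_zscore(matrix2, GeneSet("s", members))
        assert z_after.iloc[2] == pytest.approx(z_before.iloc[2])

    def test_empty_intersection_rejected(self, matrix):
        with pytest.raises(ValueError):
            gene_set_zscore(matrix, GeneSet("none", frozenset({"nope"})))

    def test_zscore_table_skips_foreign_sets(self, matrix):
        sets = [
            GeneSet("in", frozenset({"g1", "g2"})),
            GeneSet("out", frozenset({"nope"})),
        ]
        table = zscore_table(matrix, sets)
        assert list(table.index) == ["in"]


class TestTopGenes:
    @pytest.fixture()
    def matrix(self):
        values = np.array(
            [[3.0, 3.0], [1.0, 1.0], [2.0, 2.0], [2.0, 2.0], [0.0, 0.0]]
        )
        return ExpressionMatrix(
            pd.DataFrame(values, index=["g4", "g0", "g3", "g1", "g2"],
                         columns=["s1", "s2"]),
            scale="log10-qnorm-centered",
        )

    def test_ranking_with_stable_tie_break(self, matrix):
        spot = make_spot("A", ["g0", "g1", "g2", "g3", "g4"])
        ranked = top_genes(spot, matrix, ["s1", "s2"], k=10)
        assert len(ranked) == 5  # k beyond spot size returns the full list
        assert list(ranked["gene_id"]) == ["g4", "g1", "g3", "g0", "g2"]  # ties by ID

    def test_top1_matches_argmax_scan(self, matrix):
        spot = make_spot("A", ["g0", "g2", "g3"])
        ranked = top_genes(spot, matrix, ["s1"], k=1)
        sub = matrix.df.loc[["g0", "g2", "g3"], ["s1"]].mean(axis=1)
        assert ranked.loc[0, "gene_id"] == sub.idxmax()

    def test_invalid_k_rejected(self, matrix):
        with pytest.raises(ValueError):
            top_genes(make_spot("A", ["g0"]), matrix, ["s1"], k=0)


class TestSetCounts:
    def test_counts_match_brute_force_and_conserve(self):
        spots = [make_spot("A", ["g1", "g2"]), make_spot("B", ["g3"]),
                 make_spot("C", ["g4", "g5"])]
        union = GeneSet("u", frozenset({"g1", "g2", "g3", "g4", "g5"}))
        counts = setcount_per_spot(spots, union)
        assert counts.sum() == 5
        disjoint = GeneSet("d", frozenset({"x", "y"}))
        assert (setcount_per_spot(spots, disjoint) == 0).all()
        some = GeneSet("s", frozenset({"g2", "g4", "zz"}))
        counts = setcount_per_spot(spots, some)
        for spot in spots:
            assert counts[spot.label] == len(set(spot.member_genes) & some.members)


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("a", frozenset({"g1", "g2"}), "first"),
                GeneSet("b", frozenset({"g3"}))]
        path = write_gmt_sets(sets, tmp_path / "sets.gmt")
        loaded = read_gmt(path)
        assert {s.name: s.members for s in loaded} == {s.name: s.members for s in sets}

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="3 fields"):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("empty", frozenset())
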