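"""Jaccard decomposition vs a set-enumeration oracle, UPGMA ultrametricity,
branch-length beta on trees, and the spatial/temporal aggregation rules."""

import numpy as np
import pandas as pd
import pytest

import drytraits as dt
from drytraits.beta import BetaError, FunctionalTree
from drytraits.community import CommunityData


def jaccard_oracle(sa, sb):
    """Decomposition by explicit enumeration over the union."""
    shared = unique_a = unique_b = 0
    for t in sa | sb:
        if t in sa and t in sb:
            shared += 1
        elif t in sa:
            unique_a += 1
        else:
            unique_b += 1
    denom = shared + unique_a + unique_b
    return (
        (unique_a + unique_b) / denom,
        2 * min(unique_a, unique_b) / denom,
        abs(unique_a - unique_b) / denom,
    )


class TestJaccardComponents:
    def test_identical_sets_zero(self):
        d = dt.jaccard_components({"a", "b"}, {"a", "b"})
        assert (d.total, d.replacement, d.richness_difference) == (0, 0, 0)

    def test_hand_counts(self):
        d = dt.jaccard_components({"t1", "t2", "t3"}, {"t2", "t3", "t4", "t5"})
        assert d.total == pytest.approx(0.6)
        assert d.replacement == pytest.approx(0.4)
        assert d.richness_difference == pytest.approx(0.2)

    def test_disjoint_equal_sets_pure_replacement(self):
        d = dt.jaccard_components({"a", "b"}, {"c", "d"})
        assert d.total == 1.0
        assert d.replacement == 1.0
        assert d.richness_difference == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(BetaError):
            dt.jaccard_components(set(), {"a"})

    def test_matches_enumeration_oracle_on_1000_random_pairs(self):
        rng = np.random.default_rng(5)
        pool = [f"t{i}" for i in range(30)]
        for _ in range(1000):
            sa = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            sb = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            d = dt.jaccard_components(sa, sb)
            tot, rep, ric = jaccard_oracle(sa, sb)
            assert d.replacement == rep and d.richness_difference == ric
            assert d.total == pytest.approx(tot, abs=1e-12)
            assert abs(d.total - (d.replacement + d.richness_difference)) <= 1e-12

    def test_nested_sets_have_zero_replacement(self):
        d = dt.jaccard_components({"a", "b", "c", "d"}, {"a", "b"})
        assert d.replacement == 0.0
        assert d.richness_difference == d.total


class TestUPGMA:
    def _dist(self, labels, values):
        return pd.DataFrame(values, index=labels, columns=labels, dtype=float)

    def test_two_taxa_merge_at_their_distance(self):
        d = self._dist(["A", "B"], [[0, 3], [3, 0]])
        dendro = dt.upgma(d)
        assert dendro.heights[0] == pytest.approx(3.0)
        tree = FunctionalTree.from_dendrogram(dendro)
        # ultrametric: each leaf sits at depth d/2 below the root
        assert tree.length[tree.parent >= 0].sum() == pytest.approx(3.0)

    def test_three_taxa_averaging(self):
        d = self._dist(["A", "B", "C"], [[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        dendro = dt.upgma(d)
        assert np.allclose(dendro.heights, [2.0, 8.0])

    def test_ultrametric_three_point_condition_on_random_matrices(self):
        rng = np.random.default_rng(11)
        from scipy.spatial.distance import squareform

        for _ in range(500):
            n = 8
            condensed = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
            labels = [f"x{i}" for i in range(n)]
            dendro = dt.upgma(self._dist(labels, squareform(condensed)))
            coph = squareform(dendro.cophenetic())
            for i in range(n):
                for j in range(i + 1, n):
                    for k in range(j + 1, n):
                        trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
                        assert trio[1] == pytest.approx(trio[2], abs=1e-9)

    def test_missing_distances_rejected(self):
        d = self._dist(["A", "B"], [[0, np.nan], [np.nan, 0]])
        with pytest.raises(BetaError, match="missing"):
            dt.upgma(d)


class TestTreeBeta:
    def test_identical_communities_zero(self):
        tree = FunctionalTree.star(["t1", "t2", "t3"])
        d = dt.tree_beta_components({"t1", "t2"}, {"t1", "t2"}, tree)
        assert (d.total, d.replacement, d.richness_difference) == (0, 0, 0)

    def test_star_tree_hand_accounting(self):
        tree = FunctionalTree.star(["t1", "t2", "t3"])
        d = dt.tree_beta_components({"t1", "t2"}, {"t3"}, tree)
        assert d.total == pytest.approx(1.0)
        assert d.replacement == pytest.approx(2 / 3)
        assert d.richness_difference == pytest.approx(1 / 3)

    def test_star_tree_reduces_to_set_jaccard_on_200_pairs(self):
        rng = np.random.default_rng(9)
        leaves = [f"t{i}" for i in range(25)]
        tree = FunctionalTree.star(leaves)
        for _ in range(200):
            sa = set(rng.choice(leaves, size=rng.integers(1, 20), replace=False))
            sb = set(rng.choice(leaves, size=rng.integers(1, 20), replace=False))
            ts = dt.tree_beta_components(sa, sb, tree)
            ss = dt.jaccard_components(sa, sb)
            assert ts.total == pytest.approx(ss.total, abs=1e-12)
            assert ts.replacement == pytest.approx(ss.replacement, abs=1e-12)
            assert ts.richness_difference == pytest.approx(ss.richness_difference, abs=1e-12)

    def test_components_bounded_and_additive_on_upgma_tree(self, trait_db):
        gower = dt.gower_distance(trait_db)
        tree = FunctionalTree.from_dendrogram(dt.upgma(gower))
        rng = np.random.default_rng(13)
        taxa = trait_db.taxa
        for _ in range(200):
            sa = set(rng.choice(taxa, size=rng.integers(1, 40), replace=False))
            sb = set(rng.choice(taxa, size=rng.integers(1, 40), replace=False))
            d = dt.tree_beta_components(sa, sb, tree)
            assert 0 <= d.replacement <= d.total <= 1
            assert abs(d.total - (d.replacement + d.richness_difference)) <= 1e-12

    def test_unknown_leaf_rejected(self):
        tree = FunctionalTree.star(["t1", "t2"])
        with pytest.raises(BetaError, match="not in tree"):
            dt.tree_beta_components({"t1"}, {"zz"}, tree)


def _community(rows):
    records = pd.DataFrame(rows, columns=["river", "site", "date", "taxon", "abundance"])
    fi_map = {"s1": 0.0, "s2": 20.0, "s3": 40.0, "s4": 60.0, "s5": 80.0}
    fi = records[["river", "site"]].drop_duplicates()
    fi["fi"] = fi["site"].map(fi_map)
    return CommunityData(records=records, fi=fi)


class TestSpatialTemporalAggregation:
    def test_river_date_below_min_sites_excluded(self):
        rows = [("R", f"s{i}", "d1", "A", 1.0) for i in (1, 2, 3)]
        com = _community(rows)
        summaries, excluded = dt.spatial_beta(com, tree=None, min_sites=4)
        assert summaries == []
        assert len(excluded) == 1 and "3 sites" in excluded[0]

    def test_four_sites_average_six_pairs(self):
        rows = []
        taxa = {"s1": ["A", "B"], "s2": ["A", "C"], "s3": ["B", "C"], "s4": ["A", "B"]}
        for s, ts in taxa.items():
            rows += [("R", s, "d1", t, 1.0) for t in ts]
        com = _community(rows)
        summaries, _ = dt.spatial_beta(com, tree=None, min_sites=4)
        assert len(summaries) == 1
        assert summaries[0].n_pairs == 6
        assert summaries[0].fi == pytest.approx(np.mean([0, 20, 40, 60]))

    def test_identical_compositions_give_zero(self):
        rows = [("R", f"s{i}", "d1", t, 1.0) for i in (1, 2, 3, 4) for t in ("A", "B")]
        com = _community(rows)
        summaries, _ = dt.spatial_beta(com, tree=None)
        assert summaries[0].total == 0.0

    def test_temporal_pairs_and_exclusions(self):
        rows = [("R", "s1", f"d{k}", "A", 1.0) for k in range(1, 6)]
        rows += [("R", "s1", "d1", "B", 1.0)]  # composition changes once
        rows += [("R", "s2", "d1", "A", 1.0)]  # single date -> excluded
        com = _community(rows)
        summaries, excluded = dt.temporal_beta(com, tree=None)
        assert len(summaries) == 1
        assert summaries[0].n_pairs == 10
        assert summaries[0].fi == pytest.approx(0.0)
        assert len(excluded) == 1 and "s2" in excluded[0]

    def test_functional_family_emitted_with_tree(self, trait_db, community):
        gower = dt.gower_distance(trait_db)
        tree = dt.upgma(gower)
        summaries, _ = dt.spatial_beta(community, tree, min_sites=4)
        fams = {s.family for s in summaries}
        assert fams == {"taxonomic", "functional"}
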