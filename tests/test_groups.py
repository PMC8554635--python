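"""FCA against an independent correspondence-analysis oracle, Ward against
explicit variance recomputation, evenness-based partition selection, alpha
diversity and the Functional Redundancy Index."""

import numpy as np
import pandas as pd
import pytest

import drytraits as dt
from drytraits.groups import GroupingError, pielou_evenness
from drytraits.scheme import TraitScheme
from drytraits.traits import normalize_fuzzy


def ca_eigenvalues_oracle(table: np.ndarray) -> np.ndarray:
    """Correspondence analysis via the chi-square metric on row profiles
    (weighted PCA formulation), independent of the SVD route."""
    x = np.asarray(table, dtype=float)
    total = x.sum()
    r = x.sum(axis=1) / total
    c = x.sum(axis=0) / total
    profiles = x / x.sum(axis=1, keepdims=True)
    m = (profiles - c) / np.sqrt(c)
    s = (m.T * r) @ m
    eig = np.linalg.eigvalsh(s)[::-1]
    return eig[eig > 1e-12]


def ward_heights_oracle(points: np.ndarray) -> np.ndarray:
    """Greedy minimum-variance agglomeration with the within-cluster error
    sum of squares recomputed from scratch at every step."""
    clusters = [[i] for i in range(len(points))]

    def ess(idx):
        pts = points[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        heights.append(np.sqrt(2.0 * delta))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)


class TestFCA:
    def test_two_point_table_has_single_axis(self):
        scheme = TraitScheme(traits=("t",), modalities={"t": ("a", "b")})
        db = normalize_fuzzy(np.array([[1, 0], [0, 1.0]]), scheme, taxa=["A", "B"])
        res = dt.fca(db)
        assert res.n_axes_retained == 1
        assert res.inertia_proportions[0] == pytest.approx(100.0)

    def test_identical_taxa_rejected(self):
        scheme = TraitScheme(traits=("t",), modalities={"t": ("a", "b")})
        db = normalize_fuzzy(np.tile([0.5, 0.5], (4, 1)), scheme)
        with pytest.raises(GroupingError, match="variability"):
            dt.fca(db)

    def test_eigenvalues_match_independent_oracle(self):
        rng = np.random.default_rng(42)
        scheme = TraitScheme(
            traits=("t1", "t2", "t3"),
            modalities={"t1": ("a", "b", "c"), "t2": ("x", "y", "z"), "t3": ("u", "v")},
        )
        raw = rng.dirichlet(np.ones(3), size=(20, 2)).reshape(20, 6)
        table = np.column_stack([raw, rng.dirichlet(np.ones(2), size=20)])
        db = normalize_fuzzy(table, scheme)
        res = dt.fca(db, n_axes=8)
        expected = ca_eigenvalues_oracle(db.affinity.to_numpy())
        assert np.allclose(res.eigenvalues[: len(expected)], expected, atol=1e-8)

    def test_inertia_sums_to_100_and_transition_formula(self, trait_db):
        res = dt.fca(trait_db, n_axes=6)
        assert res.inertia_proportions.sum() == pytest.approx(100.0, abs=1e-9)
        # row score = D_r^-1 P G / sqrt(lambda), CA transition relation
        x = trait_db.affinity.to_numpy()
        keep = x.sum(axis=0) > 0
        p = x[:, keep] / x.sum()
        r = p.sum(axis=1)
        g = res.modality_scores.to_numpy()
        lam = res.eigenvalues[: res.n_axes_retained]
        f_expected = (p @ g) / r[:, None] / np.sqrt(lam)
        assert np.allclose(res.taxon_scores.to_numpy(), f_expected, atol=1e-8)


class TestWard:
    def test_two_singletons_merge_at_their_distance(self):
        d = dt.ward_cluster(np.array([[0.0], [1.0]]))
        assert d.heights[0] == pytest.approx(1.0)

    def test_merge_order_on_a_line(self):
        d = dt.ward_cluster(np.array([[0.0], [1.0], [10.0]]))
        first = set(d.linkage[0, :2].astype(int))
        assert first == {0, 1}
        assert d.heights[-1] > d.heights[0]

    def test_heights_match_variance_recomputation_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 6))
        d = dt.ward_cluster(pts)
        expected = ward_heights_oracle(pts)
        assert np.allclose(np.sort(d.heights), np.sort(expected), atol=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(GroupingError, match="finite"):
            dt.ward_cluster(np.array([[0.0], [np.nan]]))


class TestSelectPartition:
    def test_equal_groups_have_evenness_one(self):
        assert pielou_evenness([5, 5, 5]) == pytest.approx(1.0)

    def test_uneven_groups_evenness_hand_value(self):
        # sizes (13,1,1): J = -(13/15 ln 13/15 + 2 * 1/15 ln 1/15)/ln 3
        assert pielou_evenness([13, 1, 1]) == pytest.approx(0.4416, abs=1e-3)

    def test_ties_break_toward_fewer_groups(self):
        # 4 equidistant-ish singleton pairs: J(2) = J(4) = 1 -> g = 2
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        dendro = dt.ward_cluster(pts)
        grouping = dt.select_partition(dendro, 2, 4)
        assert grouping.n_groups == 2

    def test_partition_invariant_under_leaf_relabeling(self, trait_db):
        res = dt.fca(trait_db)
        scores = res.taxon_scores
        grouping = dt.select_partition(dt.ward_cluster(scores), 2, 15)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(scores))
        scores2 = scores.iloc[perm]
        grouping2 = dt.select_partition(dt.ward_cluster(scores2), 2, 15)
        # same partition as sets of taxa
        def blocks(g):
            return sorted(
                tuple(sorted(g.assignment.index[g.assignment == k]))
                for k in range(1, g.n_groups + 1)
            )
        assert blocks(grouping) == blocks(grouping2)

    def test_degenerate_range_rejected(self, trait_db):
        dendro = dt.ward_cluster(dt.fca(trait_db).taxon_scores)
        with pytest.raises(GroupingError):
            dt.select_partition(dendro, 1, 5)
        with pytest.raises(GroupingError):
            dt.select_partition(dendro, 10, 5)


class TestAlphaDiversity:
    def test_counts_taxa_and_groups(self):
        rel = pd.DataFrame({"A": [0.5], "B": [0.3], "C": [0.2], "D": [0.0]},
                           index=["s1"])
        grouping = dt.FunctionalGrouping(
            assignment=pd.Series({"A": 1, "B": 1, "C": 2, "D": 3}), n_groups=3)
        alpha = dt.alpha_diversity(rel, grouping)
        assert alpha.loc["s1", "taxonomic_richness"] == 3
        assert alpha.loc["s1", "functional_richness"] == 2

    def test_functional_bounded_by_taxonomic_and_group_count(self, rel_abund, trait_db):
        grouping = dt.select_partition(
            dt.ward_cluster(dt.fca(trait_db).taxon_scores), 2, 15)
        alpha = dt.alpha_diversity(rel_abund, grouping)
        assert (alpha["functional_richness"]
                <= np.minimum(alpha["taxonomic_richness"], grouping.n_groups)).all()

    def test_empty_site_rejected(self):
        rel = pd.DataFrame({"A": [0.0]}, index=["s1"])
        grouping = dt.FunctionalGrouping(assignment=pd.Series({"A": 1}), n_groups=1)
        with pytest.raises(GroupingError, match="empty"):
            dt.alpha_diversity(rel, grouping)


class TestFRI:
    def _grouping(self):
        taxa = [f"t{i}" for i in range(9)]
        # group 1: t0..t4 (5 taxa), group 2: t5..t8 (4 taxa)
        return dt.FunctionalGrouping(
            assignment=pd.Series({t: (1 if i < 5 else 2) for i, t in enumerate(taxa)}),
            n_groups=2)

    def test_hand_example_weighted_site_fri(self):
        grouping = self._grouping()
        # pool site makes N_max: group1 -> 5, group2 -> 4
        pool = {f"t{i}": 0.1 for i in range(9)}
        # site: 3 taxa of group 1 (w=0.6), 1 taxon of group 2 (w=0.4)
        site = {"t0": 0.2, "t1": 0.2, "t2": 0.2, "t5": 0.4}
        rel = pd.DataFrame([pool, site], index=["pool", "s1"]).fillna(0.0)
        rivers = pd.Series({"pool": "R", "s1": "R"})
        res = dt.fri(rel, grouping, rivers)
        # FRI_1 = 100*(3-1)/(5-1) = 50, FRI_2 = 0 -> site = 0.6*50
        assert res.per_site["s1"] == pytest.approx(30.0)

    def test_endpoints_zero_and_hundred(self):
        grouping = self._grouping()
        full = {f"t{i}": 1 / 9 for i in range(9)}
        single = {"t0": 1.0}
        rel = pd.DataFrame([full, single], index=["s_full", "s_single"]).fillna(0.0)
        rivers = pd.Series({"s_full": "R", "s_single": "R"})
        res = dt.fri(rel, grouping, rivers)
        assert res.per_site["s_full"] == pytest.approx(100.0)
        assert res.per_site["s_single"] == pytest.approx(0.0)

    def test_degenerate_group_with_single_pool_taxon_scores_zero(self):
        grouping = dt.FunctionalGrouping(
            assignment=pd.Series({"A": 1, "B": 2}), n_groups=2)
        rel = pd.DataFrame({"A": [0.5, 1.0], "B": [0.5, 0.0]}, index=["s1", "s2"])
        res = dt.fri(rel, grouping, pd.Series({"s1": "R", "s2": "R"}))
        # each group holds one taxon in the river pool: no redundancy possible
        assert res.per_site["s1"] == pytest.approx(0.0)

    def test_bounds_and_max_condition_on_synthetic(self, rel_abund, trait_db, community):
        grouping = dt.select_partition(
            dt.ward_cluster(dt.fca(trait_db).taxon_scores), 2, 15)
        res = dt.fri(rel_abund, grouping, community.river_of_site())
        assert res.per_site.between(0, 100).all()
        at_max = res.per_group.groupby("site").apply(
            lambda g: bool((g["n_taxa"] == g["n_max"]).all()), include_groups=False)
        for site, full in at_max.items():
            if full:
                assert res.per_site[site] == pytest.approx(100.0)

    def test_missing_river_rejected(self):
        grouping = dt.FunctionalGrouping(assignment=pd.Series({"A": 1, "B": 2}),
                                         n_groups=2)
        rel = pd.DataFrame({"A": [1.0], "B": [0.0]}, index=["s1"])
        with pytest.raises(GroupingError, match="river"):
            dt.fri(rel, grouping, pd.Series(dtype=object))
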