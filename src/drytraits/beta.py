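"""Pairwise beta diversity decomposed into replacement and richness difference.

Taxonomic beta diversity uses the presence-absence Jaccard index partitioned
into two additive components (Podani family): with a shared taxa and b, c
unique to either community,

    total               = (b + c) / (a + b + c)
    replacement         = 2 min(b, c) / (a + b + c)
    richness difference = |b - c| / (a + b + c)

Functional beta diversity applies the same formulas to branch lengths of a
UPGMA dendrogram built on Gower trait distances: a, b, c become the branch
length shared by, or unique to, the root-spanning subtrees of the two
communities.  Spatial beta averages site pairs within a river and sampling
date (skipping river-dates with fewer than ``min_sites`` sites); temporal
beta averages date pairs within a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .community import CommunityData
from .groups import Dendrogram

__all__ = [
    "BetaDecomposition", "BetaSummary", "FunctionalTree",
    "jaccard_components", "upgma", "tree_beta_components",
    "spatial_beta", "temporal_beta",
]


class BetaError(ValueError):
    """Raised for undefined beta-diversity comparisons."""


@dataclass(frozen=True)
class BetaDecomposition:
    """Additive decomposition of one pairwise dissimilarity."""

    total: float
    replacement: float
    richness_difference: float
    family: str  # "jaccard-set" | "jaccard-tree"

    def __post_init__(self) -> None:
        if abs(self.total - (self.replacement + self.richness_difference)) > 1e-12:
            raise BetaError("components do not sum to the total")


def _decompose(a: float, b: float, c: float, family: str) -> BetaDecomposition:
    denom = a + b + c
    if denom <= 0:
        raise BetaError("both communities empty: decomposition undefined")
    repl = 2.0 * min(b, c) / denom
    rich = abs(b - c) / denom
    return BetaDecomposition(
        total=repl + rich, replacement=repl, richness_difference=rich, family=family
    )


def jaccard_components(presence_a: set[str], presence_b: set[str]) -> BetaDecomposition:
    """Jaccard dissimilarity between two taxon sets, decomposed."""
    if not presence_a or not presence_b:
        raise BetaError("presence sets must be nonempty")
    a = len(presence_a & presence_b)
    b = len(presence_a - presence_b)
    c = len(presence_b - presence_a)
    return _decompose(a, b, c, "jaccard-set")


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram from a square distance matrix.

    Average linkage on the condensed distances; merge heights are the
    average between-cluster distances (ultrametric: a pair of taxa at
    distance d merges at height d, each leaf sitting at depth d/2).
    """
    if not isinstance(dist, pd.DataFrame) or dist.shape[0] != dist.shape[1]:
        raise BetaError("distance matrix must be square and labelled")
    values = dist.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise BetaError("distance matrix contains missing values")
    from scipy.spatial.distance import squareform

    z = hierarchy.linkage(squareform(values, checks=False), method="average")
    return Dendrogram(labels=[str(t) for t in dist.index], linkage=z, method="upgma")


@dataclass
class FunctionalTree:
    """Rooted tree with branch lengths, indexed for branch-length beta.

    ``parent[i]``/``length[i]`` give each node's parent edge; ``leafsets``
    is a nodes x leaves boolean matrix marking the leaves under each node.
    The root carries no edge.
    """

    leaves: list[str]
    parent: np.ndarray
    length: np.ndarray
    leafsets: np.ndarray
    _leaf_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._leaf_index = {t: i for i, t in enumerate(self.leaves)}

    @classmethod
    def from_dendrogram(cls, dendro: Dendrogram) -> "FunctionalTree":
        """Convert a dendrogram; UPGMA node heights are merge height / 2."""
        scale = 0.5 if dendro.method == "upgma" else 1.0
        root = hierarchy.to_tree(dendro.linkage)
        n_leaves = dendro.n_leaves
        leaves = dendro.labels
        nodes: list = []

        def collect(node):
            nodes.append(node)
            if not node.is_leaf():
                collect(node.left)
                collect(node.right)

        collect(root)
        index = {id(node): i for i, node in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        leafsets = np.zeros((len(nodes), n_leaves), dtype=bool)

        def heights(node) -> float:
            return 0.0 if node.is_leaf() else node.dist * scale

        def walk(node):
            i = index[id(node)]
            if node.is_leaf():
                leafsets[i, node.id] = True
                return
            for child in (node.left, node.right):
                j = index[id(child)]
                parent[j] = i
                length[j] = heights(node) - heights(child)
                walk(child)
                leafsets[i] |= leafsets[j]

        walk(root)
        return cls(leaves=list(leaves), parent=parent, length=length, leafsets=leafsets)

    @classmethod
    def star(cls, leaves: list[str], branch_length: float = 1.0) -> "FunctionalTree":
        """Star tree: every leaf attached to the root by an equal branch."""
        n = len(leaves)
        parent = np.concatenate([[-1], np.zeros(n, dtype=int)])
        length = np.concatenate([[0.0], np.full(n, branch_length)])
        leafsets = np.zeros((n + 1, n), dtype=bool)
        leafsets[0] = True
        leafsets[1:] = np.eye(n, dtype=bool)
        return cls(leaves=list(leaves), parent=parent, length=length, leafsets=leafsets)

    def community_mask(self, presence: set[str]) -> np.ndarray:
        missing = sorted(t for t in presence if t not in self._leaf_index)
        if missing:
            raise BetaError(f"leaves not in tree: {missing}")
        mask = np.zeros(len(self.leaves), dtype=bool)
        for t in presence:
            mask[self._leaf_index[t]] = True
        return mask

    def branch_use(self, presence: set[str]) -> np.ndarray:
        """Edges on paths from the root to the community's leaves."""
        mask = self.community_mask(presence)
        return (self.leafsets @ mask) > 0


def tree_beta_components(presence_a: set[str], presence_b: set[str],
                         tree: FunctionalTree | Dendrogram) -> BetaDecomposition:
    """Branch-length Jaccard decomposition on a functional dendrogram."""
    if not presence_a or not presence_b:
        raise BetaError("presence sets must be nonempty")
    if isinstance(tree, Dendrogram):
        tree = FunctionalTree.from_dendrogram(tree)
    use_a = tree.branch_use(presence_a)
    use_b = tree.branch_use(presence_b)
    a = float(tree.length[use_a & use_b].sum())
    b = float(tree.length[use_a & ~use_b].sum())
    c = float(tree.length[use_b & ~use_a].sum())
    return _decompose(a, b, c, "jaccard-tree")


@dataclass
class BetaSummary:
    """Averaged pairwise beta components for one aggregation unit.

    ``scope`` is "spatial" (unit = river-date, pairs = site pairs, FI = mean
    site FI on that date) or "temporal" (unit = site, pairs = date pairs,
    FI = site FI).
    """

    scope: str
    unit: str
    river: str
    fi: float
    family: str
    total: float
    replacement: float
    richness_difference: float
    n_pairs: int


def _presence_by(records: pd.DataFrame) -> pd.DataFrame:
    return (
        records.groupby(["site", "date", "taxon"])["abundance"].sum().gt(0).unstack(
            "taxon", fill_value=False
        )
    )


def _pair_means(sets: list[set[str]], tree: FunctionalTree | None):
    """Average set-family (and, if a tree is given, tree-family) components
    over all pairs."""
    fams = {}
    n = len(sets)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    set_vals = np.array(
        [
            (d.total, d.replacement, d.richness_difference)
            for i, j in pairs
            for d in [jaccard_components(sets[i], sets[j])]
        ]
    )
    fams["taxonomic"] = set_vals.mean(axis=0)
    if tree is not None:
        tree_vals = np.array(
            [
                (d.total, d.replacement, d.richness_difference)
                for i, j in pairs
                for d in [tree_beta_components(sets[i], sets[j], tree)]
            ]
        )
        fams["functional"] = tree_vals.mean(axis=0)
    return fams, len(pairs)


def spatial_beta(community: CommunityData, tree: FunctionalTree | Dendrogram | None = None,
                 min_sites: int = 4) -> tuple[list[BetaSummary], list[str]]:
    """Among-site beta diversity per river and sampling date.

    For each (river, date) with at least ``min_sites`` sampled sites, each
    component is averaged over all site pairs; the FI covariate is the mean
    FI of that date's sites.  River-dates below the threshold are skipped
    and returned in the exclusion log.
    """
    if isinstance(tree, Dendrogram):
        tree = FunctionalTree.from_dendrogram(tree)
    presence = _presence_by(community.records)
    site_fi = community.site_fi()
    river_of = community.river_of_site()
    out: list[BetaSummary] = []
    excluded: list[str] = []
    sampled = presence.index.to_frame(index=False)
    sampled["river"] = river_of.loc[sampled["site"]].values
    for (river, date), grp in sampled.groupby(["river", "date"]):
        sites = sorted(grp["site"])
        if len(sites) < min_sites:
            excluded.append(f"{river}@{date}: {len(sites)} sites < {min_sites}")
            continue
        sets = [
            set(presence.columns[presence.loc[(s, date)].to_numpy()]) for s in sites
        ]
        fi = float(site_fi.loc[sites].mean())
        fams, n_pairs = _pair_means(sets, tree)
        for family, (tot, repl, rich) in fams.items():
            out.append(BetaSummary("spatial", f"{river}@{date}", river, fi, family,
                                   tot, repl, rich, n_pairs))
    return out, excluded


def temporal_beta(community: CommunityData,
                  tree: FunctionalTree | Dendrogram | None = None
                  ) -> tuple[list[BetaSummary], list[str]]:
    """Among-date beta diversity per site (sites with >= 2 dates)."""
    if isinstance(tree, Dendrogram):
        tree = FunctionalTree.from_dendrogram(tree)
    presence = _presence_by(community.records)
    site_fi = community.site_fi()
    river_of = community.river_of_site()
    out: list[BetaSummary] = []
    excluded: list[str] = []
    for site, block in presence.groupby(level="site"):
        dates = sorted(block.index.get_level_values("date"))
        if len(dates) < 2:
            excluded.append(f"{site}: {len(dates)} date(s) < 2")
            continue
        sets = [
            set(block.columns[block.loc[(site, d)].to_numpy()]) for d in dates
        ]
        fams, n_pairs = _pair_means(sets, tree)
        for family, (tot, repl, rich) in fams.items():
            out.append(BetaSummary("temporal", site, str(river_of.loc[site]),
                                   float(site_fi.loc[site]), family,
                                   tot, repl, rich, n_pairs))
    return out, excluded


def beta_table(summaries: list[BetaSummary]) -> pd.DataFrame:
    """Tidy table of beta summaries."""
    return pd.DataFrame([vars(s) for s in summaries])
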