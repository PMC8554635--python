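"""Functional groups from fuzzy trait profiles, alpha diversity, and redundancy.

Pipeline: a correspondence analysis of the fuzzy-coded trait table (FCA)
summarizes trait variability among taxa on a few axes; Ward minimum-variance
clustering of the taxon scores builds a dendrogram; the partition maximizing
Pielou evenness of group sizes defines the functional groups.  From a
grouping, per-site taxonomic and functional richness and the Functional
Redundancy Index (FRI) follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .traits import TraitDatabase

_RANK_TOL = 1e-12


class GroupingError(ValueError):
    """Raised for degenerate inputs to the grouping pipeline."""


@dataclass
class FCAResult:
    """Correspondence analysis of a fuzzy trait table.

    ``eigenvalues`` are squared singular values of the standardized residual
    matrix (descending, over all axes); ``inertia_proportions`` are their
    percentages of total inertia; ``taxon_scores`` are principal row
    coordinates and ``modality_scores`` principal column coordinates on the
    retained axes.
    """

    eigenvalues: np.ndarray
    inertia_proportions: np.ndarray
    taxon_scores: pd.DataFrame
    modality_scores: pd.DataFrame
    n_axes_retained: int

    @property
    def retained_inertia_pct(self) -> float:
        """Percentage of total inertia carried by the retained axes."""
        return float(self.inertia_proportions[: self.n_axes_retained].sum())


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over labelled leaves.

    Wraps a scipy linkage matrix; ``heights`` (column 2) are on the distance
    scale: with Ward linkage two singletons merge at their Euclidean
    distance, with UPGMA at their average distance (ultrametric).
    """

    labels: list[str]
    linkage: np.ndarray
    method: str  # "ward" | "upgma"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise GroupingError("linkage matrix shape does not match leaf count")
        h = self.heights
        if np.any(np.diff(h) < -1e-9):
            raise GroupingError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, g: int) -> pd.Series:
        """Partition the leaves into ``g`` clusters (ids 1..g)."""
        if not (1 <= g <= self.n_leaves):
            raise GroupingError(f"cannot cut {self.n_leaves} leaves into {g} groups")
        flat = hierarchy.fcluster(self.linkage, t=g, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="group")

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances (merge height joining each pair)."""
        from scipy.spatial.distance import squareform

        return hierarchy.cophenet(self.linkage)

    def to_newick(self, halve_heights: bool | None = None) -> str:
        """Newick string with branch lengths from merge heights.

        For UPGMA trees node height is merge height / 2 (ultrametric depth);
        for Ward trees the raw merge height is used.
        """
        if halve_heights is None:
            halve_heights = self.method == "upgma"
        scale = 0.5 if halve_heights else 1.0
        tree = hierarchy.to_tree(self.linkage)

        def node_height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist * scale

        def render(node, parent_h: float) -> str:
            length = parent_h - node_height(node)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node_height(node))
            right = render(node.right, node_height(node))
            return f"({left},{right}):{length:.10g}"

        root_h = node_height(tree)
        left = render(tree.left, root_h)
        right = render(tree.right, root_h)
        return f"({left},{right});"


@dataclass
class FunctionalGrouping:
    """Assignment of every taxon to exactly one functional group (ids 1..G)."""

    assignment: pd.Series  # taxon -> group id
    n_groups: int
    provenance: str = "unspecified"
    evenness_profile: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.assignment.unique())
        if ids != set(range(1, self.n_groups + 1)):
            raise GroupingError(
                f"group ids must be 1..{self.n_groups} and all nonempty, got {sorted(ids)}"
            )

    @property
    def group_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


@dataclass
class FRIResult:
    """Functional Redundancy Index per (site, group) and per site.

    ``per_group`` columns: site, group, n_taxa, n_max (river pool size for
    the group), fri (%), weight (summed relative abundance).  ``per_site``
    is the abundance-weighted site FRI in %.
    """

    per_group: pd.DataFrame
    per_site: pd.Series


def fca(trait_db: TraitDatabase, n_axes: int = 6) -> FCAResult:
    """Fuzzy correspondence analysis of the trait table.

    Standard correspondence analysis applied to the concatenated fuzzy
    table (each row sums to the taxon's number of known traits): with
    P the table over its grand total, r and c the row and column masses,
    the standardized residuals ``diag(r)^-1/2 (P - r c') diag(c)^-1/2``
    are decomposed by SVD; eigenvalues are squared singular values, taxon
    scores principal row coordinates.  Modality columns that are zero for
    every taxon carry no mass and are dropped.
    """
    if n_axes < 1:
        raise GroupingError("n_axes must be >= 1")
    if not trait_db.known_mask.any(axis=1).all():
        bad = trait_db.known_mask.index[~trait_db.known_mask.any(axis=1)]
        raise GroupingError(f"taxa with no known trait: {list(bad)}")
    x = trait_db.affinity.to_numpy(dtype=float)
    cols = trait_db.affinity.columns
    keep = x.sum(axis=0) > 0
    x = x[:, keep]
    cols = cols[keep]

    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    resid = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(resid, full_matrices=False)
    lam = sv**2
    rank = int(np.sum(lam > _RANK_TOL * max(lam.max(initial=0.0), 1.0)))
    if rank == 0:
        raise GroupingError("no trait variability (all taxa identical)")
    lam = lam[:rank]
    inertia = 100.0 * lam / lam.sum()
    k = min(n_axes, rank)

    row_coords = (u[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    col_coords = (vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
    axes = [f"axis_{i + 1}" for i in range(k)]
    return FCAResult(
        eigenvalues=lam,
        inertia_proportions=inertia,
        taxon_scores=pd.DataFrame(row_coords, index=trait_db.affinity.index, columns=axes),
        modality_scores=pd.DataFrame(col_coords, index=cols, columns=axes),
        n_axes_retained=k,
    )


def ward_cluster(scores: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Ward minimum-variance dendrogram on Euclidean distances between rows.

    Heights are on the distance scale (the square root of twice the
    within-cluster variance increase), so two singletons merge at their
    Euclidean distance and cut heights are comparable to distances.
    """
    if isinstance(scores, pd.DataFrame):
        labels = [str(i) for i in scores.index]
        x = scores.to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        labels = [f"leaf_{i + 1}" for i in range(x.shape[0])]
    if x.shape[0] < 2:
        raise GroupingError("need at least 2 points to cluster")
    if not np.isfinite(x).all():
        raise GroupingError("non-finite coordinates")
    z = hierarchy.linkage(x, method="ward")
    return Dendrogram(labels=labels, linkage=z, method="ward")


def pielou_evenness(sizes: np.ndarray | list[int]) -> float:
    """Normalized Shannon entropy of group-size proportions (1 = even)."""
    sizes = np.asarray(sizes, dtype=float)
    g = len(sizes)
    if g < 2:
        return 1.0
    p = sizes / sizes.sum()
    h = -np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))
    return float(h / np.log(g))


def select_partition(dendro: Dendrogram, g_min: int = 2, g_max: int = 25) -> FunctionalGrouping:
    """Cut the dendrogram at the group count maximizing size evenness.

    For each g in [g_min, g_max] the tree is cut into g groups and Pielou
    evenness J(g) of the group-size proportions is computed; the partition
    with maximal J wins, ties broken toward fewer groups.  The full J(g)
    profile is kept for inspection.
    """
    n = dendro.n_leaves
    if not (2 <= g_min <= g_max <= n):
        raise GroupingError(f"need 2 <= g_min <= g_max <= {n}")
    profile: dict[int, float] = {}
    best_g, best_j, best_cut = None, -np.inf, None
    for g in range(g_min, g_max + 1):
        cut = dendro.cut(g)
        j = pielou_evenness(cut.value_counts().to_numpy())
        profile[g] = j
        if j > best_j + 1e-12:
            best_g, best_j, best_cut = g, j, cut
    # renumber groups by first appearance for label stability
    order = {old: new + 1 for new, old in enumerate(dict.fromkeys(best_cut))}
    assignment = best_cut.map(order)
    return FunctionalGrouping(
        assignment=assignment,
        n_groups=len(order),
        provenance=f"evenness cut g={best_g} (J={best_j:.4f})",
        evenness_profile=profile,
    )


def alpha_diversity(rel_abund: pd.DataFrame, grouping: FunctionalGrouping) -> pd.DataFrame:
    """Per-site taxonomic and functional richness.

    Taxonomic richness counts taxa with positive relative abundance;
    functional richness counts the distinct functional groups among them.
    """
    missing = sorted(set(rel_abund.columns) - set(grouping.assignment.index))
    if missing:
        raise GroupingError(f"taxa not covered by grouping: {missing}")
    present = rel_abund.to_numpy() > 0
    if not present.any(axis=1).all():
        empty = list(rel_abund.index[~present.any(axis=1)])
        raise GroupingError(f"empty sampling units: {empty}")
    groups = grouping.assignment.loc[rel_abund.columns].to_numpy()
    tax = present.sum(axis=1)
    fun = [len(np.unique(groups[row])) for row in present]
    return pd.DataFrame(
        {"taxonomic_richness": tax, "functional_richness": fun}, index=rel_abund.index
    )


def fri(rel_abund: pd.DataFrame, grouping: FunctionalGrouping,
        river_of_site: pd.Series) -> FRIResult:
    """Functional Redundancy Index, anchored per river.

    For group k at a site, with n observed taxa of that group and N_max the
    number of taxa of that group recorded anywhere in the same river,
    FRI_k = 100 (n - 1) / (N_max - 1) when N_max >= 2, else 0 (a group whose
    river pool holds a single taxon cannot be redundant).  The site FRI is
    the average of FRI_k over groups present, weighted by their summed
    relative abundances.
    """
    missing = sorted(set(rel_abund.index) - set(river_of_site.index))
    if missing:
        raise GroupingError(f"sites without river assignment: {missing}")
    taxa = list(rel_abund.columns)
    groups = grouping.assignment.loc[taxa]
    present = rel_abund > 0

    # river pool size per (river, group): taxa of the group seen anywhere in the river
    rivers = river_of_site.loc[rel_abund.index]
    n_max: dict[tuple[str, int], int] = {}
    for river, sites in rel_abund.groupby(rivers.values):
        pool = present.loc[sites.index].any(axis=0)
        pool_taxa = [t for t in taxa if pool[t]]
        counts = groups.loc[pool_taxa].value_counts()
        for g in range(1, grouping.n_groups + 1):
            n_max[(river, g)] = int(counts.get(g, 0))

    rows = []
    site_fri = {}
    for site in rel_abund.index:
        river = rivers[site]
        w = rel_abund.loc[site]
        here = w[w > 0]
        by_group = here.groupby(groups.loc[here.index].values)
        total, wsum = 0.0, 0.0
        for g, members in by_group:
            n = len(members)
            nm = n_max[(river, int(g))]
            fri_k = 100.0 * (n - 1) / (nm - 1) if nm >= 2 else 0.0
            weight = float(members.sum())
            rows.append({"site": site, "group": int(g), "n_taxa": n,
                         "n_max": nm, "fri": fri_k, "weight": weight})
            total += weight * fri_k
            wsum += weight
        site_fri[site] = total / wsum
    per_group = pd.DataFrame(rows)
    per_site = pd.Series(site_fri, name="fri").reindex(rel_abund.index)
    return FRIResult(per_group=per_group, per_site=per_site)
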