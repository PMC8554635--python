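"""Fuzzy trait coding, community-weighted trait profiles and Gower distances.

Fuzzy coding describes each taxon's affinity for the modalities of a trait
with nonnegative scores; dividing each taxon-by-trait block by its sum makes
the affinities comparable across taxa (they sum to 1 per trait).  Traits for
which a taxon has no information (an all-zero block) are kept as zeros and
flagged unknown, and are excluded pairwise from distances and renormalized
out of community-weighted means rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityData
from .scheme import TraitScheme

_BLOCK_TOL = 1e-9


class TraitTableError(ValueError):
    """Raised for malformed fuzzy trait tables."""


@dataclass
class TraitDatabase:
    """Fuzzy-coded trait table: taxa x (trait, modality) affinities.

    ``affinity`` has a two-level column index (trait, modality) in scheme
    order; for every (taxon, trait) with ``known_mask`` true the block sums
    to 1 within 1e-9, unknown blocks are all-zero.
    """

    scheme: TraitScheme
    affinity: pd.DataFrame  # index: taxa, columns: MultiIndex (trait, modality)
    known_mask: pd.DataFrame  # index: taxa, columns: traits (bool)

    def __post_init__(self) -> None:
        values = self.affinity.to_numpy(dtype=float)
        if (values < -_BLOCK_TOL).any():
            raise TraitTableError("negative affinities")
        for trait, sl in self.scheme.block_slices().items():
            sums = values[:, sl].sum(axis=1)
            known = self.known_mask[trait].to_numpy(dtype=bool)
            if not np.allclose(sums[known], 1.0, atol=_BLOCK_TOL):
                raise TraitTableError(f"known {trait!r} blocks do not sum to 1")
            if not np.allclose(sums[~known], 0.0, atol=_BLOCK_TOL):
                raise TraitTableError(f"unknown {trait!r} blocks are not all-zero")

    @property
    def taxa(self) -> list[str]:
        return list(self.affinity.index)

    @property
    def n_taxa(self) -> int:
        return len(self.affinity)

    def resistance_scores(self) -> pd.Series:
        """Mean normalized affinity over the scheme's resistance modalities."""
        idx = self.scheme.resistance_column_indices()
        if not idx:
            return pd.Series(0.0, index=self.affinity.index)
        return pd.Series(
            self.affinity.to_numpy(dtype=float)[:, idx].mean(axis=1),
            index=self.affinity.index,
        )


@dataclass
class CommunityTraitProfile:
    """Community-weighted mean (CWM) trait profiles.

    ``values``: samples x (trait, modality) weighted-mean affinities,
    renormalized within each trait over the taxa with known information so
    entries sum to 1 whenever ``coverage`` (summed relative abundance of
    those taxa) is positive.
    """

    scheme: TraitScheme
    values: pd.DataFrame
    coverage: pd.DataFrame  # samples x traits


def _columns_index(scheme: TraitScheme) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(scheme.columns, names=["trait", "modality"])


def normalize_fuzzy(raw: pd.DataFrame | np.ndarray, scheme: TraitScheme,
                    taxa: list[str] | None = None) -> TraitDatabase:
    """Normalize raw fuzzy scores block-wise so each known trait sums to 1.

    Parameters
    ----------
    raw
        Taxa x modality nonnegative scores with columns in scheme order
        (a DataFrame index supplies taxon labels unless ``taxa`` is given).
    scheme
        Trait/modality layout matching the columns of ``raw``.

    All-zero blocks (no information for that taxon and trait) are left zero
    and flagged unknown.  Already-normalized tables pass through unchanged
    (the operation is idempotent).
    """
    if isinstance(raw, pd.DataFrame):
        values = raw.to_numpy(dtype=float)
        if taxa is None:
            taxa = [str(t) for t in raw.index]
    else:
        values = np.asarray(raw, dtype=float)
        if taxa is None:
            taxa = [f"taxon_{i + 1}" for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[1] != scheme.n_columns:
        raise TraitTableError(
            f"expected {scheme.n_columns} modality columns, got {values.shape}"
        )
    if (values < 0).any():
        rows = np.unique(np.nonzero(values < 0)[0])
        raise TraitTableError(f"negative scores in rows {rows.tolist()}")

    norm = np.zeros_like(values)
    known = {}
    for trait, sl in scheme.block_slices().items():
        block = values[:, sl]
        sums = block.sum(axis=1)
        ok = sums > 0
        norm[ok, sl] = block[ok] / sums[ok, None]
        known[trait] = ok
    affinity = pd.DataFrame(norm, index=pd.Index(taxa, name="taxon"),
                            columns=_columns_index(scheme))
    mask = pd.DataFrame(known, index=affinity.index)[list(scheme.traits)]
    return TraitDatabase(scheme=scheme, affinity=affinity, known_mask=mask)


def relative_abundances(community: CommunityData, level: str = "site") -> pd.DataFrame:
    """Relative abundance table at the chosen aggregation level.

    level='site': raw abundances are first averaged across each site's
    sampling dates (absences on a date count as zero) and then divided by
    the site total, following the date-averaging convention used for alpha
    diversity and trait profiles.  level='site-date': each sample is
    normalized by its own total.

    Returns a wide table (rows: site or (site, date); columns: taxa)
    whose rows sum to 1.
    """
    rec = community.records
    per_sample = (
        rec.groupby(["site", "date", "taxon"], sort=True)["abundance"]
        .sum()
        .unstack("taxon", fill_value=0.0)
    )
    if level == "site-date":
        table = per_sample
    elif level == "site":
        table = per_sample.groupby(level="site", sort=True).mean()
    else:
        raise ValueError(f"unknown level {level!r}")
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise TraitTableError(f"all-zero sampling units: {list(zero.index)}")
    return table.div(totals, axis=0)


def community_trait_profile(rel_abund: pd.DataFrame | pd.Series,
                            trait_db: TraitDatabase) -> CommunityTraitProfile:
    """Abundance-weighted mean trait profile of each community.

    Per modality, the weighted mean is the sum over taxa of relative
    abundance x affinity; within each trait the result is renormalized over
    the taxa whose trait is known, so entries sum to 1 whenever coverage
    (summed relative abundance of covered taxa) is positive.
    """
    if isinstance(rel_abund, pd.Series):
        rel = rel_abund.to_frame().T
    else:
        rel = rel_abund
    missing = sorted(set(rel.columns) - set(trait_db.taxa))
    if missing:
        raise TraitTableError(f"taxa missing from trait database: {missing}")

    aff = trait_db.affinity.loc[list(rel.columns)]
    w = rel.to_numpy(dtype=float)  # samples x taxa
    a = aff.to_numpy(dtype=float)  # taxa x columns
    raw = w @ a
    known = trait_db.known_mask.loc[list(rel.columns)].to_numpy(dtype=bool)

    out = np.zeros_like(raw)
    cov = {}
    for j, (trait, sl) in enumerate(trait_db.scheme.block_slices().items()):
        coverage = w @ known[:, j].astype(float)
        cov[trait] = coverage
        ok = coverage > 0
        out[ok, sl] = raw[ok, sl] / coverage[ok, None]
    values = pd.DataFrame(out, index=rel.index, columns=aff.columns)
    coverage = pd.DataFrame(cov, index=rel.index)[list(trait_db.scheme.traits)]
    return CommunityTraitProfile(scheme=trait_db.scheme, values=values, coverage=coverage)


def gower_distance(trait_db: TraitDatabase) -> pd.DataFrame:
    """Taxon-by-taxon Gower distance matrix on the fuzzy trait table.

    Every modality column is treated as quantitative: the pairwise distance
    is the mean over columns of |difference| / column range, where the range
    is taken across all taxa, restricted to columns whose trait is known for
    both taxa (pairwise exclusion of unknown blocks).  Columns with zero
    range carry no information and are skipped.  Raises if some pair shares
    no known trait.
    """
    if trait_db.n_taxa < 2:
        raise TraitTableError("need at least 2 taxa for distances")
    x = trait_db.affinity.to_numpy(dtype=float)
    n = x.shape[0]
    ranges = x.max(axis=0) - x.min(axis=0)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    known = trait_db.known_mask.to_numpy(dtype=bool)
    for j, (trait, sl) in enumerate(trait_db.scheme.block_slices().items()):
        pair_known = np.logical_and.outer(known[:, j], known[:, j])
        for c in range(sl.start, sl.stop):
            if ranges[c] <= 0:
                continue
            diff = np.abs(x[:, c, None] - x[None, :, c]) / ranges[c]
            num += np.where(pair_known, diff, 0.0)
            den += pair_known
    if (den == 0).any():
        i, j = np.nonzero(den == 0)
        pairs = [(trait_db.taxa[a], trait_db.taxa[b]) for a, b in zip(i, j) if a < b][:5]
        raise TraitTableError(f"taxon pairs share no known trait, e.g. {pairs}")
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return pd.DataFrame(d, index=trait_db.affinity.index, columns=trait_db.affinity.index)
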