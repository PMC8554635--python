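"""Synthetic trait databases and community matrices.

The generator emulates the structure of multi-river invertebrate surveys
along flow-intermittence (FI) gradients: about 14 rivers with 3-18 sites
each, 1-10 sampling dates, FI spanning 0-95% of the year, a regional pool
of a few hundred fuzzy-coded taxa, site richness declining linearly with
FI, and trait-mediated filtering in which taxa with drying-resistance
modalities persist to higher FI.  It exists so every downstream stage of
the pipeline is testable without any field dataset.

Mechanics (stand-ins, not reconstructions of any field process):

* Trait profiles are mixtures of a small number of latent archetypes,
  controlling trait syndromes; ``syndrome_strength`` interpolates between
  fully independent traits (0) and fully archetype-determined profiles (1).
* Richness decline acts by occupancy thinning: the number of taxa at a
  site is Poisson around ``baseline_richness - decline_rate * FI / 10``
  (floored at 1), and which taxa occur is a weighted draw favouring
  high-resistance taxa as FI grows (weight exp(-filtering_strength *
  (1 - resistance) * FI / 100)).  Abundance-based filtering is not used
  because all downstream metrics except CWM are presence- or
  relative-abundance-based.
* Abundances are lognormal; sampling dates are exchangeable draws with an
  optional successional-drift term (off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .community import CommunityData
from .scheme import SchemeError, TraitScheme
from .traits import TraitDatabase, normalize_fuzzy


@dataclass
class GeneratorConfig:
    """Sampling-design and filtering parameters of the community generator.

    ``sites_per_river`` and ``n_dates`` accept a count or an inclusive
    (low, high) range drawn per river.  ``decline_rate`` is taxa lost per
    10% FI; ``filtering_strength`` >= 0 scales trait-mediated occupancy
    filtering; ``abundance_dispersion`` is the log-scale s.d. of abundances.
    """

    n_rivers: int = 14
    sites_per_river: int | tuple[int, int] = (3, 18)
    n_dates: int | tuple[int, int] = (1, 10)
    fi_range: tuple[float, float] = (0.0, 95.0)
    pool_size: int = 300
    baseline_richness: float = 30.0
    decline_rate: float = 2.3
    filtering_strength: float = 2.0
    abundance_dispersion: float = 1.0
    date_presence: float = 0.85
    succession_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fi_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("fi_range must satisfy 0 <= lo <= hi <= 100")
        if self.decline_rate < 0:
            raise ValueError("decline_rate must be >= 0")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if self.pool_size < self.baseline_richness:
            raise ValueError("pool_size must be >= baseline_richness")
        if self.n_rivers < 1:
            raise ValueError("need at least one river")
        if not (0 < self.date_presence <= 1):
            raise ValueError("date_presence must be in (0, 1]")


def _draw_count(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def generate_trait_database(
    scheme: TraitScheme,
    n_taxa: int,
    syndrome_strength: float = 0.5,
    seed: int = 0,
    n_archetypes: int = 12,
    archetype_concentration: float = 0.6,
    return_archetypes: bool = False,
) -> TraitDatabase | tuple[TraitDatabase, pd.Series]:
    """Draw a fuzzy-coded trait database from latent archetypes.

    Each taxon is assigned one of ``n_archetypes`` latent archetypes (each a
    full trait profile drawn once); its observed per-trait profile is the
    convex mixture ``(1 - s) * independent + s * archetype`` with
    ``s = syndrome_strength``.  s = 0 gives independently drawn traits,
    s = 1 fully archetype-determined profiles.  Archetype frequencies are
    themselves Dirichlet(``archetype_concentration``) draws, so some trait
    syndromes are common and others rare, as in real assemblages.  Blocks
    are normalized to sum to 1 per trait by construction.
    """
    if not isinstance(scheme, TraitScheme):
        raise SchemeError("scheme must be a TraitScheme")
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not (0 <= syndrome_strength <= 1):
        raise ValueError("syndrome_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cols = scheme.n_columns
    slices = scheme.block_slices()

    # each archetype carries a latent drying-resistance level that tilts its
    # profile toward the flagged modalities across traits (trait syndromes:
    # resistant taxa are jointly small, short-lived, dormancy-capable, ...)
    resist_level = rng.uniform(size=n_archetypes)
    flagged = set(scheme.resistance_column_indices())
    arch = np.zeros((n_archetypes, n_cols))
    for sl in slices.values():
        k = sl.stop - sl.start
        flag_in_block = np.array([c in flagged for c in range(sl.start, sl.stop)])
        for a in range(n_archetypes):
            alpha = np.full(k, 0.5)
            alpha[flag_in_block] += 3.0 * resist_level[a]
            arch[a, sl] = rng.dirichlet(alpha)
    freq = rng.dirichlet(np.full(n_archetypes, archetype_concentration))
    assignment = rng.choice(n_archetypes, size=n_taxa, p=freq)

    indep = np.zeros((n_taxa, n_cols))
    for sl in slices.values():
        k = sl.stop - sl.start
        indep[:, sl] = rng.dirichlet(np.ones(k), size=n_taxa)

    s = syndrome_strength
    profiles = (1 - s) * indep + s * arch[assignment]
    taxa = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    db = normalize_fuzzy(profiles, scheme, taxa=taxa)
    if return_archetypes:
        return db, pd.Series(assignment, index=db.affinity.index, name="archetype")
    return db


def expected_richness(cfg: GeneratorConfig, fi: float | np.ndarray) -> np.ndarray:
    """Linear expected site richness, floored at 1 taxon."""
    return np.maximum(1.0, cfg.baseline_richness - cfg.decline_rate * np.asarray(fi) / 10.0)


def generate_communities(trait_db: TraitDatabase, cfg: GeneratorConfig) -> CommunityData:
    """Simulate a multi-river survey from a regional taxon pool.

    Site FI is uniform within ``cfg.fi_range``; site richness is Poisson
    around the linear decline (floored at 1); which taxa occur is a
    weighted sampling without replacement whose weights penalize
    low-resistance taxa proportionally to FI and ``filtering_strength``.
    Every occupying taxon is observed on at least one date, so the union of
    dates recovers the site assemblage and every sample is nonempty.
    """
    if trait_db.n_taxa < cfg.pool_size:
        raise ValueError(
            f"trait database has {trait_db.n_taxa} taxa, pool_size is {cfg.pool_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    pool = list(trait_db.taxa)[: cfg.pool_size]
    resistance = trait_db.resistance_scores().loc[pool].to_numpy()

    fi_lo, fi_hi = cfg.fi_range
    if cfg.baseline_richness - cfg.decline_rate * fi_hi / 10.0 < 1:
        warnings.warn(
            "expected richness < 1 at maximum FI; floor of 1 taxon applied",
            stacklevel=2,
        )
    taxon_phase = rng.uniform(size=len(pool))  # only used when drift > 0

    rows: list[tuple[str, str, str, str, float]] = []
    fi_rows: list[tuple[str, str, float]] = []
    site_truth: dict[str, dict[str, Any]] = {}
    for r in range(cfg.n_rivers):
        river = f"R{r + 1:02d}"
        n_sites = _draw_count(rng, cfg.sites_per_river)
        n_dates = _draw_count(rng, cfg.n_dates)
        for s in range(n_sites):
            site = f"{river}-S{s + 1:02d}"
            fi = float(rng.uniform(fi_lo, fi_hi))
            fi_rows.append((river, site, fi))
            mu = float(expected_richness(cfg, fi))
            k = int(np.clip(rng.poisson(mu), 1, len(pool)))
            # Gumbel top-k == weighted sampling without replacement
            logw = -cfg.filtering_strength * (1.0 - resistance) * fi / 100.0
            keys = logw + rng.gumbel(size=len(pool))
            chosen = np.argsort(keys)[::-1][:k]
            site_truth[site] = {"fi": fi, "expected_richness": mu, "richness": k}

            presence = rng.uniform(size=(k, n_dates)) < cfg.date_presence
            if cfg.succession_drift > 0 and n_dates > 1:
                frac = np.linspace(-1, 1, n_dates)
                pref = (taxon_phase[chosen, None] - 0.5) * frac[None, :]
                p = np.clip(cfg.date_presence + cfg.succession_drift * pref, 0.05, 1.0)
                presence = rng.uniform(size=(k, n_dates)) < p
            never = ~presence.any(axis=1)
            presence[never, rng.integers(0, n_dates, size=int(never.sum()))] = True

            log_mu = rng.normal(np.log(10.0), 0.5, size=k)  # taxon-level mean abundance
            for d in range(n_dates):
                date = f"D{d + 1}"
                idx = np.nonzero(presence[:, d])[0]
                if len(idx) == 0:  # unreachable: every taxon has a date
                    idx = np.array([0])
                ab = np.exp(rng.normal(log_mu[idx], cfg.abundance_dispersion))
                for i, a in zip(idx, ab):
                    rows.append((river, site, date, pool[chosen[i]], float(a)))

    records = pd.DataFrame(rows, columns=["river", "site", "date", "taxon", "abundance"])
    fi_table = pd.DataFrame(fi_rows, columns=["river", "site", "fi"])
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "sites": site_truth,
    }
    return CommunityData(records=records, fi=fi_table, truth=truth)
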