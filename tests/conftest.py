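import numpy as np
import pandas as pd
import pytest

from drytraits import (
    GeneratorConfig,
    TraitScheme,
    default_scheme,
    generate_communities,
    generate_trait_database,
)


@pytest.fixture(scope="session")
def scheme() -> TraitScheme:
    return default_scheme()


@pytest.fixture(scope="session")
def two_modality_scheme() -> TraitScheme:
    return TraitScheme(
        traits=("size", "life"),
        modalities={"size": ("small", "large"), "life": ("short", "long")},
        resistance_traits=(("size", "small"), ("life", "short")),
    )


@pytest.fixture(scope="session")
def trait_db(scheme):
    return generate_trait_database(scheme, 120, syndrome_strength=0.5, seed=101)


@pytest.fixture(scope="session")
def community(trait_db):
    cfg = GeneratorConfig(
        n_rivers=6, sites_per_river=(4, 8), n_dates=(2, 4),
        pool_size=120, baseline_richness=28.0, seed=202,
    )
    return generate_communities(trait_db, cfg)


@pytest.fixture(scope="session")
def rel_abund(community):
    from drytraits import relative_abundances

    return relative_abundances(community, level="site")


def make_presence(n_sites: int, n_taxa: int, seed: int, mean_occupancy: float = 0.4
                  ) -> pd.DataFrame:
    """Random site x taxon presence with heterogeneous site richness."""
    rng = np.random.default_rng(seed)
    occ = rng.uniform(0.1, 0.9, size=n_sites)
    mat = rng.uniform(size=(n_sites, n_taxa)) < occ[:, None] * mean_occupancy / 0.5
    for i in range(n_sites):  # no empty sites
        if not mat[i].any():
            mat[i, rng.integers(n_taxa)] = True
    return pd.DataFrame(
        mat,
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
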