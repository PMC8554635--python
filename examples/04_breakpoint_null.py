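"""Breakpoint in the functional-vs-taxonomic richness relationship, with a
random-allocation null.

If functional groups accumulated taxa at random, functional richness would
rise with taxonomic richness along a predictable saturating curve.  The
Davies test asks whether the observed relationship has a slope change; the
segmented fit locates it; and the 999-draw null (groups reallocated to taxa
uniformly at random) yields empirical p-values for the Davies p, the
breakpoint location and both slopes.
"""

import drytraits as dt

scheme = dt.default_scheme()
trait_db = dt.generate_trait_database(scheme, n_taxa=300, seed=1)
community = dt.generate_communities(trait_db, dt.GeneratorConfig(seed=2))
rel = dt.relative_abundances(community, level="site")

grouping = dt.select_partition(
    dt.ward_cluster(dt.fca(trait_db).taxon_scores), 2, 25)
alpha = dt.alpha_diversity(rel, grouping)

x = alpha["taxonomic_richness"].to_numpy(dtype=float)
y = alpha["functional_richness"].to_numpy(dtype=float)
print(f"{len(x)} sites, {grouping.n_groups} functional groups")
print(f"Davies test p = {dt.davies_test(x, y):.2e} (breakpoint present?)")

fit = dt.segmented_fit(x, y)
print(f"breakpoint at {fit.psi:.1f} taxa "
      f"(95% CI {fit.psi_ci95[0]:.1f}-{fit.psi_ci95[1]:.1f}); "
      f"slopes {fit.slope_before:.2f} before vs {fit.slope_after:.2f} after")

ens = dt.redundancy_null(rel.gt(0), grouping, n_sim=999, seed=3)
print("empirical p-values against the random-allocation null "
      f"({ens.n_valid} valid simulations):")
for name, p in ens.p_values.items():
    print(f"  {name}: {p:.3f}")
print("-> a flat after-breakpoint slope that the null cannot reproduce is "
      "the signature of functional redundancy at richer sites")
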