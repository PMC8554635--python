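# Methods

This note documents the models and procedures implemented in `drytraits`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Fuzzy trait coding and community profiles

A taxon's trait profile is fuzzy-coded: nonnegative affinity scores over
the modalities of each trait, divided by the per-trait block sum so that
every known trait block sums to 1. Blocks that are all zero (no
autecological information) are kept as zeros and flagged unknown — they are
excluded pairwise from distances and renormalized out of community means
rather than imputed, so no autecology is fabricated. Normalization is
idempotent, which lets the trait-CSV reader accept raw integer scores and
already-normalized tables through the same path.

Community-weighted mean (CWM) profiles are the abundance-weighted mean
affinities per modality. Within each trait the weighted mean is
renormalized over the taxa whose trait is known, so per-trait sums stay at
1 under partial knowledge; the coverage (summed relative abundance of
covered taxa) is reported alongside so a profile resting on little
information is visible.

Relative abundances follow the survey convention: per site, raw abundances
are first averaged over that site's sampling dates (absence on a sampled
date counts as zero) and then divided by the site total. Beta diversity
instead uses per-date presences — temporal beta would be undefined on
date-averaged data; the averaging convention is read as applying to alpha
diversity and trait profiles.

## Gower distances

Every modality column is treated as quantitative on [0, 1] with global
range normalization: the distance between two taxa is the mean over
modality columns of |difference| / column range, restricted to columns
whose trait is known for both taxa. Columns with zero range are skipped
(they carry no information). A pair sharing no known trait is an error
surfaced before clustering. Under this construction, distances are
symmetric, bounded by [0, 1], and satisfy the triangle inequality; the test
suite asserts this numerically on random taxon triples.

## Fuzzy correspondence analysis and functional groups

FCA is correspondence analysis applied to the concatenated fuzzy table
(each row sums to the taxon's number of known traits). With P the table
over its grand total, r and c the row/column masses, the standardized
residual matrix `diag(r)^-1/2 (P − r c') diag(c)^-1/2` is decomposed by
SVD; eigenvalues are squared singular values, taxon scores are principal
row coordinates, modality scores principal column coordinates. All-zero
modality columns carry no mass and are dropped. The default of six retained
axes is configurable. Correctness is anchored by an independent oracle in
the tests — the chi-square-metric weighted PCA of row profiles — agreeing
to 1e-8, and by the CA transition formula as an invariant.

Functional groups come from Ward minimum-variance clustering of the taxon
scores. Heights are reported on the distance scale (the square root of
twice the within-cluster variance increase), so two singletons merge at
their Euclidean distance and cut heights are comparable to distances; a
from-scratch variance-recomputation oracle confirms the merge heights to
1e-10. The number of groups is chosen by cutting the dendrogram at every g
in a range (default 2–25) and keeping the partition maximizing Pielou
evenness `J(g) = −Σ p_i ln p_i / ln g` of group-size proportions, ties
broken toward fewer groups; the full J(g) profile is returned for
inspection. This makes an essentially visual judgement ("shape of the
dendrogram") reproducible.

## Functional redundancy index

For group k at a site with n_k observed taxa, and N_max the number of taxa
of that group recorded anywhere in the same river (the river pool, not the
regional pool — groups span continents, rivers do not),

    FRI_k = 100 (n_k − 1) / (N_max − 1)   if N_max ≥ 2, else 0.

A group whose river pool holds a single taxon cannot be redundant and is
anchored at 0%. The site FRI averages FRI_k over the groups present,
weighted by their summed relative abundances; it equals 100 exactly when
every group present attains its river maximum.

## Beta diversity decomposition

Pairwise presence–absence Jaccard dissimilarity is partitioned into two
additive components: replacement `2·min(b,c)/(a+b+c)` and richness
difference `|b−c|/(a+b+c)`, with a shared and b, c unique units. For
functional beta the units are branch lengths on the UPGMA dendrogram of
Gower distances: each community claims the edges on root-to-leaf paths of
its members (the root-spanning subtree; the minimum spanning alternative
was considered and not adopted — the root-spanning form reduces exactly to
the set-based decomposition on unit star trees, which the tests exploit as
an identity). UPGMA node heights are merge height / 2, making the tree
ultrametric; the three-point condition is asserted on random matrices.

Spatial beta averages all site pairs within a river and sampling date and
attaches the mean FI of those sites; river-dates with fewer than four sites
are skipped and logged. Temporal beta averages date pairs within a site and
attaches the site FI; sites with fewer than two dates are skipped and
logged.

## Breakpoint, Davies test and the random-allocation null

The functional-vs-taxonomic richness relationship, pooled across all
sites, is characterized by three pieces:

**Davies test.** For k = 10 candidate breakpoints evenly spaced between
the 2nd and (n−1)th order statistics of x, the Wald statistic t_j of the
hinge term (x − ψ_j)+ added to the linear fit is computed; with
M = max|t_j| and V the total variation of the sequence, the bound
`p = min(1, 2Φ(−M) + V exp(−M²/2)/√(8π))` is returned. Because the Wald
statistics have estimated variance they are t-distributed, not normal; each
is mapped through its t-distribution to an equivalent normal score before
the bound is applied. Without this correction the finite-sample size at
n ≤ 100 exceeds the nominal level; with it, the empirical size at the
0.05 level over 1000 linear-null simulations (n = 216, the pooled sample
size the models use) is ≈ 0.048. Residual variance at float-noise level
(exactly collinear or noiseless-linear data) yields p = 1.

**Segmented regression.** The working model
`y ~ 1 + x + (x − ψ)+ + V`, `V = −1{x > ψ}`, is iteratively refitted with
the update ψ ← ψ + γ̂/β̂ (γ̂ the V coefficient, β̂ the hinge coefficient),
with two numerical safeguards: updates are step-halved against the
broken-line profile RSS so the iteration cannot oscillate around a kink,
and the iteration is multi-started (median, profile-scan minima, outer
quantiles), keeping the converged fit with the lowest profile RSS. This
makes the estimator agree with a 200-point profile-likelihood grid search
within one grid step on all tested datasets. The breakpoint standard error
is se(γ̂)/|β̂| and the 95% CI is ψ ± 1.96 se — the standard delta
construction. Its coverage is a known limitation: at moderate noise
(e.g. slopes 0.32/0.11, σ = 1.5, n = 216) simulations put the true coverage
near 86–90%, not 95%; the CI is anticonservative whenever the profile
minimum sits at a kink. Users needing calibrated breakpoint intervals
should invert the profile or bootstrap.

**Random-allocation null.** Each of n_sim simulations reassigns functional
groups to taxa — by default independently and uniformly over the observed
number of groups (`mode="uniform"`, matching the description of random
allocation); a size-preserving permutation mode is available — then
recomputes per-site functional richness and re-characterizes the
relationship. Empirical p-values use the add-one rule
`(1 + #{as or more extreme}) / (n_sim + 1)` with per-parameter tails:
slope-before lower, slope-after two-sided, ψ upper, Davies-p lower (the
directions in which redundancy departs from chance). Failed simulated fits
are flagged and excluded from the counts with the valid n reported. When
the observed grouping is itself a uniform draw, all four empirical
p-values are uniform (self-consistency, verified by simulation).

## Mixed models, LRTs and R²

All gradient models are Gaussian random-intercept models fitted by maximum
likelihood (statsmodels MixedLM; sites nested in rivers enter as a
variance component). ML is used throughout because fixed effects are
tested by likelihood-ratio tests between nested fits — chi-square with df
equal to the parameter difference (df = 1 for single-term tests); REML is
available but rejected by `lrt`. Marginal and conditional R² are the
fixed and fixed-plus-random variance fractions of the total (fixed-effect
predictor variance, summed random-intercept variances, residual variance).
Singular fits pin the offending variance at zero rather than failing; with
a truly absent group effect the fixed estimates collapse to OLS. The model
battery mirrors the study design: z-scaled richness ~ FI × richness type
with river and site-in-river intercepts; raw-scale richness ~ FI per type
(the decline per 10% FI); FRI ~ FI and FRI ~ taxonomic richness with river
intercepts; functional ~ taxonomic spatial beta; and each beta component ~
FI with river intercepts. `slope_to_raw` converts a z-scale slope back to
raw units per Δ FI as `slope_z × sd(response) × Δ`.

## Trait-trend trees

For one trait, the per-sample CWM profile (modalities summing to 1) is
tested for association with FI using the linear statistic T = Σ fi_i Y_i,
standardized component-wise by its Monte-Carlo permutation moments and
summarized by the maximum absolute standardized component; the p-value is
the add-one fraction of permutations with a larger statistic. A max-type
statistic was chosen over a quadratic form because it names the modality
driving a shift. When significant at α, the node splits at the FI
threshold maximizing the analogous two-sample statistic (analytic
permutation moments), subject to a minimum leaf size of 5, and recursion
continues; nodes with constant FI or too few samples are leaves. With a
single numeric predictor there is no variable-selection layer, so no
Bonferroni step is needed. Detection of a planted profile step at FI = 50
lands in [40, 60] in essentially all simulated replicates; the false-split
rate under a null generator matches α within simulation error.

## Synthetic-data generator

The generator defines the study conditions for all tests: ~14 rivers with
3–18 sites, 1–10 sampling dates, FI uniform on 0–95%, a 300-taxon
fuzzy-coded pool, baseline richness 30 taxa declining 2.3 per 10% FI.

* **Trait database.** Taxa mix an independent Dirichlet draw with one of
  12 latent archetypes (`syndrome_strength`, default 0.5, interpolates; 0 =
  independent traits, 1 = archetype-determined). Archetype frequencies are
  themselves Dirichlet(0.6) draws, so some syndromes are common and others
  rare — without this, evenness-based partition selection collapses onto a
  handful of balanced clusters no real trait table shows. Each archetype
  carries a latent drying-resistance level tilting its profile toward the
  flagged resistance modalities across traits, reflecting that resistance
  traits covary (resistant taxa are jointly small, short-lived,
  dormancy-capable); without that covariance, averaging twelve independent
  blocks compresses the resistance score into a band too narrow to filter
  on.
* **Communities.** Site richness is Poisson around the linear decline,
  floored at one taxon; which taxa occur is weighted sampling without
  replacement (Gumbel top-k) with weights
  `exp(−filtering_strength (1 − resistance) FI/100)`, resistance being the
  mean affinity over flagged modalities. The decline acts by occupancy
  thinning, not abundance scaling, because every downstream metric except
  the CWM is presence- or relative-abundance-based. Abundances are
  lognormal around taxon-level means (log-scale sd 1 by default); each
  occupying taxon is observed on at least one date, so every sample is
  nonempty and the site assemblage equals the union over dates. Dates are
  exchangeable; an optional successional-drift term (default off) induces
  directional temporal turnover.
* **What it does not emulate.** No spatial structure of FI along a
  network, no dispersal limitation, no hydrological dynamics, no
  taxonomic-resolution noise, and (by default) no succession — so the
  generator's temporal beta carries no FI trend, and passing tests show the
  estimators recover what was planted, not that real rivers behave this
  way. Field effects mediated by mechanisms outside the generator (e.g.
  recolonization dynamics) are outside what these tests can certify.

## Problem sizes and numerical conventions

Test simulations are sized for a single CPU: 1000 linear-null datasets for
the Davies size check, 200 replicate datasets at n_sim = 199 for the
null-ensemble uniformity check, 500 simulations for LRT calibration, 500
replicates for breakpoint-CI coverage, 100 for mixed-model recovery, 200
for trend-tree power, and a full 14-river end-to-end run with a 999-draw
null. Key tolerances: trait-block sums 1e-9, decomposition additivity
1e-12, FCA oracle 1e-8, Ward oracle 1e-10. Ties in evenness selection break
toward fewer groups; group ids are renumbered by first appearance so
partitions are label-stable; empirical p-values always use the add-one
rule and therefore never return zero.
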