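# drytraits

Trait-based analysis of how stream macroinvertebrate communities respond —
taxonomically and functionally — to **flow intermittence** (FI, the
percentage of the year a river site has no surface flow).

Rivers worldwide are shifting from perennial to intermittent flow regimes.
A central question for freshwater ecologists is whether **functional
redundancy** (several taxa sharing the same trait profile) buffers the loss
of taxa as drying intensifies. `drytraits` packages the full analysis chain
used to answer it:

1. **Fuzzy trait coding** — each taxon's affinity for the modalities of 12
   biological traits, normalized so affinities sum to 1 per trait.
2. **Functional groups** — fuzzy correspondence analysis (FCA) of the trait
   table, Ward minimum-variance clustering of taxon scores on the leading
   axes, and selection of the partition maximizing Pielou evenness of group
   sizes.
3. **Alpha diversity and redundancy** — per-site taxonomic and functional
   richness, and the Functional Redundancy Index
   `FRI_k = 100 (n_k − 1)/(N_max − 1)` (0% = a group represented by a single
   taxon, 100% = the river-pool maximum), averaged over groups weighted by
   relative abundance.
4. **Beta diversity** — pairwise Jaccard dissimilarity partitioned into
   additive **replacement** `2·min(b,c)/(a+b+c)` and **richness difference**
   `|b−c|/(a+b+c)` components; the functional analogue applies the same
   formulas to branch lengths of a UPGMA dendrogram built on Gower trait
   distances. Spatial beta averages site pairs per river and date (≥ 4
   sites); temporal beta averages date pairs per site.
5. **Breakpoint and null model** — the Davies test for a slope change in
   the functional-vs-taxonomic richness relationship, segmented (broken
   line) regression locating the breakpoint ψ with slopes before/after, and
   an empirical null that reallocates functional groups to taxa at random
   (add-one empirical p-values for ψ, both slopes and the Davies p).
6. **Gradient models** — Gaussian mixed models with river (and site nested
   in river) random intercepts, likelihood-ratio tests of fixed effects,
   marginal/conditional R², and permutation-based conditional-inference
   trees locating FI thresholds where community-weighted trait profiles
   shift.

A first-class **synthetic-data generator** emulates the structure of
multi-river surveys (14 rivers, 3–18 sites each, FI 0–95%, a pool of a few
hundred fuzzy-coded taxa, linear richness decline with FI, trait-mediated
filtering), so the whole pipeline runs and is tested without any field
download.

## Worked example

```bash
python examples/04_breakpoint_null.py
```

prints, for a 148-site synthetic survey with 23 functional groups:

```
148 sites, 23 functional groups
Davies test p = 2.05e-07 (breakpoint present?)
breakpoint at 17.0 taxa (95% CI 14.7-19.3); slopes 0.63 before vs 0.28 after
empirical p-values against the random-allocation null (999 valid simulations):
  davies_p: 0.444
  psi: 0.612
  slope_before: 0.393
  slope_after: 0.628
```

Reading: the richness–richness relationship bends at ~17 taxa — above that,
extra taxa add few new functional groups (the slope drops from 0.63 to
0.28). The empirical p-values then ask whether that saturation is any
stronger than expected from randomly assembled groups of the same number;
here (a randomly structured synthetic community) it is not. The remaining
examples cover the generator (`01`), functional groups and FRI (`02`), beta
decomposition (`03`) and the mixed-model battery with trait-trend trees
(`05`); each prints its numbers with a line on what they mean.

A thin CLI mirrors the library:

```bash
drytraits simulate --out data --seed 1
drytraits run-all --traits data/traits.csv --community data/community.csv \
    --fi data/fi.csv --nsim 999 --seed 1 --out results_run
```

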