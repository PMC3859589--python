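# metasucc

Landscape-scale analysis of secondary-forest succession from chronosequence
inventories: diversity, composition, spatial structure, and the
conservation value of ephemeral regrowth.

## The problem

In human-modified tropical landscapes, most forest is young regrowth on
abandoned fields and pastures.  Whether such a shifting patchwork of
short-lived secondary forests can sustain tree diversity depends on two
questions that must be answered at the scale of the *metacommunity* — the
set of local stands linked by dispersal — rather than at single plots:

1. Is succession *deterministic* across the landscape?  I.e., do diversity
   and composition change predictably with stand age and stand basal area
   (SBA), and is that change driven by species turnover (dispersal-limited
   recruitment) or by reshuffling of local dominance (the successional
   niche)?
2. How many species actually reach **reproductive size** before a fallow is
   recleared — the "effective γ-diversity" of the metacommunity?

`metasucc` implements the full statistical pipeline for this design — a
replicated chronosequence of sites (each a slope with two 20 × 50 m plots;
seedling, sapling, tree and liana strata censused at different effort) —
plus a mechanistic synthetic-metacommunity generator so the entire pipeline
is testable without any field download.

## Methods implemented

* **Hill diversity** ^qD = (Σᵢ pᵢ^q)^(1/(1−q)), with ¹D = exp(−Σ pᵢ ln pᵢ);
  exact (hypergeometric) individual-based rarefaction E[Sₙ]; sample-based
  accumulation curves; γ-diversity of site classes by resampling 12 sites
  1000 times with 0.025/0.975 quantile confidence limits.
* **Compositional dissimilarity**: Ružička (abundance-based Jaccard)
  d = 1 − Σ min(xᵢ,yᵢ)/Σ max(xᵢ,yᵢ), its presence/absence version, the
  Morisita–Horn alternative, and the **Chao–Jaccard abundance estimator**
  with the unseen-shared-species correction — the right tool when one
  sample (seedlings) is far smaller than the other (trees).
* **NMDS** minimizing Kruskal stress-1 with isotonic regression, multiple
  random starts, Procrustes convergence diagnostics, PCA rotation of the
  configuration, and a frequent-species sensitivity analysis.
* **Permutational statistics**: Mantel tests and correlograms against
  geographic distance (progressive Holm correction), and one-factor
  PERMANOVA (pseudo-F from the Gower-centered distance matrix) with
  exhaustive enumeration at small n.
* **Succession regressions**: linear, power (y = a·x^b) and exponential
  (y = a·e^{bx}) fits of any community metric on age, SBA or understory
  light, compared by response-scale R² with an F-test significance screen.
* **Landscape frequencies**: per-species occurrence (F₁) and local
  dominance (F₅%) percentages across plots, between-class species turnover,
  and rank-frequency curves with a log-scale decay slope.
* **Effective diversity**: species classified into six maximum-DBH classes
  (1–5 … >80 cm, class mid-value as a conservative DBH_max); a species
  counts as reproductively viable in an age class when some individual
  exceeds a **relative size threshold** (RST, 10% or 30% of DBH_max),
  optionally in more than one plot.

## Worked example

```python
from metasucc import (assign_classes, build_abundance_matrix,
                      generate_metacommunity, nmds, pairwise_dissimilarity,
                      permanova, select_model)
from metasucc.conservation import effective_gamma_summary

stems, sites, traits = generate_metacommunity(seed=1)

trees = build_abundance_matrix(stems, "tree", "site", all_units=list(sites.index))
sel = select_model(sites.sba_m2ha.to_numpy(),
                   trees.df.gt(0).sum(axis=1).to_numpy(float))
print(f"tree 0D vs SBA: model {sel.code}, R^2 = {sel.r2:.2f}")

dm = pairwise_dissimilarity(
    build_abundance_matrix(stems, ("sapling", "tree", "liana"), "site",
                           min_diameter_cm=1.0), "ruzicka")
print(f"NMDS stress (k=2): {nmds(dm, k=2, n_starts=10, seed=2).stress:.3f}")

sba = assign_classes(sites, "sba")
print(permanova(dm, [sba.membership[u] for u in dm.units],
                permutations=999, seed=3))

for label, s in effective_gamma_summary(stems, traits,
                                        assign_classes(sites, "age")).items():
    print(f"{label}: {s.n_species_total} species, "
          f"{s.n_species_above[0.30]} above RST30 "
          f"({s.reduction_pct(0.30)}% reduction)")
```

prints

```
tree 0D vs SBA: model L, R^2 = 0.53
NMDS stress (k=2): 0.140
PERMANOVA: F = 3.055, R^2 = 0.127, df = (2, 42), p = 0.001
2-7 y: 211 species, 78 above RST30 (63% reduction)
8-17 y: 221 species, 154 above RST30 (30% reduction)
18-32 y: 227 species, 198 above RST30 (13% reduction)
```

Tree species density rises deterministically with stand basal area; the
stand-basal-area classes explain a modest but highly significant share of
compositional variation; and while the oldest stands carry nearly all of
their species pool above the 30% reproductive-size threshold, the youngest
age class holds mature-sized individuals for barely a third of its species
— the signature of ephemeral secondary forests as a biased, reproductively
immature sample of the regional pool.

There is also a CLI over CSV/YAML files:

```bash
metasucc simulate --scenario paper-like --seed 1 --outdir data/
metasucc all --seed 1 --outdir results/   # full pipeline + hashed manifest
```

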