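# Methods notes

This note documents the models, numerical choices and known limitations of
`metasucc`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design assumed by the data model

A *site* is a single slope with one upper and one lower 20 × 50 m plot.
Four strata are censused with different effort per plot: seedlings
(20–80 cm tall, no diameter; twenty 1 m² subplots = 20 m²), saplings
(1 ≤ DBH < 5 cm, half plot = 500 m²), trees (DBH ≥ 5 cm, full plot) and
lianas (climbers ≥ 1 cm, full plot).  Sites are grouped into three stand
basal area classes ([0, 11), [11, 20), [20, 30) m² ha⁻¹ — half-open, so an
exact boundary value belongs to the upper class and a closed lower bound at
0 leaves no site unassignable) and three age classes (2–7, 8–17, 18–32 y,
closed integer intervals).  When site basal area is not supplied it is
computed from all stems ≥ 1 cm as Σ π(d/2)² scaled by each stratum's own
sampled area; lianas are included by default and excludable by flag, since
field conventions differ on whether climbers count toward stand basal area.

Unidentified stems are retained under their morphospecies codes; rows coded
as unknown can be dropped with a flag.  Validation is per-row: a stem whose
diameter contradicts its stratum is rejected and reported, never silently
fixed.

## Synthetic metacommunity generator

The generator is first-class code, not a fixture: it encodes exactly the two
processes the statistics downstream are meant to detect.

**Dispersal limitation.** Colonization rates vary log-normally across the
species pool (median 0.06 arrivals · site⁻¹ · y⁻¹, log-sd 1.0), so landscape
occupancy accumulates at very different speeds across species.  Cumulative
arrivals at a site of age T are Poisson(rate · T) with uniform arrival
times.

**The successional niche.** Stand basal area follows a saturating curve
SBA(t) = 30 · t/(t + 8) with site-level log-normal noise (sd 0.25), clipped
to the 0.5–29.5 m² ha⁻¹ span of the site-selection design; understory light
declines as light% = 100 · exp(−0.086 · SBA), ≈ 7.6% at SBA 30 — a typical
closed-canopy value.  An arrival establishes with probability
s + (1 − s) · l², where l is the light fraction at arrival and s the
species' shade tolerance.  The quadratic light term makes recruitment
effectively gap-limited: establishment is near-certain for everyone in
young, open stands but collapses to the species' tolerance under canopy.
(A linear light term was considered and rejected: it floors closed-canopy
establishment at the light fraction itself, ~10–15% through mid-succession,
which is too permissive to drive the shade-intolerant guild out of older
stands.)  Pioneers (15% of the pool) colonize 6× faster, tolerate little
shade (Beta(1, 14)), grow fast (≈ 2.2 cm y⁻¹) and die young (≈ 12 y
longevity, constant hazard 1/longevity); everything else is slower, more
tolerant, longer-lived, and spans all six maximum-size classes.  Diameters
grow as growth · residence with multiplicative noise, capped at 0.95 ×
the species' maximum-DBH class mid-value.

**Census emulation.** Survivors are emitted as stems with the stratum their
diameter implies; saplings are thinned binomially to the half-plot sampling
area.  Seedlings are drawn directly as Poisson counts of last-2-year
establishments (a seed-rain multiplier × the 2% subplot-area fraction)
because at the generator's stem densities thinning grown stems to 20 m²
would leave almost no seedlings; they carry no diameter.  The paper-like
scenario uses 45 sites (15 per age class, ages drawn uniformly within each
class) and a 300-species pool — the study's design — but stem densities are
kept a few-fold below field values so the whole pipeline runs in seconds;
all rates are parameters, not constants.

**What the generator does not emulate**: seed banks, resprouting, explicit
disperser behavior, within-plot spatial structure, soil heterogeneity,
measurement error in diameters, or taxonomic mis-identification.  Passing
tests therefore demonstrate that the *statistics* recover a known regime of
dispersal limitation plus niche turnover; they say nothing about whether a
particular field system is in that regime.

An optional exponential colonization kernel (range 150 m) around per-species
source points creates short-range compositional autocorrelation for
exercising the Mantel correlogram; it is off by default.  A null scenario
emits i.i.d. Poisson counts with log-normally varying species means and no
age, basal-area or spatial signal, for calibrating type-I error.

Every table derives from one master seed through independent spawned
streams; identical parameters and seed give byte-identical output.

## Diversity

Hill numbers use the closed-form Shannon limit at q = 1 — never a numerical
approach to 1 — so the profile is exact and continuous.  Rarefaction is the
exact hypergeometric expectation evaluated with log-gamma arithmetic
(stable for N in the millions).  Resampled γ-diversity pools 12 sites drawn
*without* replacement per iteration (with-replacement is available behind a
flag) and reports empirical 0.025/0.975 quantiles with linear
interpolation; 12 sites and 1000 iterations are defaults, not magic — class
γ for equal-sized classes can also be computed by pooling all sites.
Accumulation curves default to the exact combinatorial expectation over
random site orderings, with a Monte-Carlo mode retained mainly to verify it.

## Similarity

The Chao–Jaccard abundance estimator follows the corrected form: with
shared-species set S12 and sample totals n, m,
U = Σ_{S12} xᵢ/n + ((m−1)/m) · f₊₁/(2 f₊₂) · Σ_{S12} (xᵢ/n)·1[yᵢ = 1],
V symmetric, both capped at 1, similarity UV/(U + V − UV).  When a sample
has no doubletons among shared species (f₊₂ = 0) the denominator uses
2(f₊₂ + 1), the usual bias-correction convention.  No shared species is a
legitimate 0, not an error.  The uncorrected variant is available for
sensitivity checks.  The seedling-divergence analysis filters both
assemblages to species whose maximum-DBH class mid-value is ≥ 7.5 cm
(i.e. species that can reach ≥ 5 cm DBH), scores all cross pairs of
seedling units against reference units, and reports the mean with a
normal-theory 95% CI across pairs (pairs treated as independent; a
bootstrap CI is available — cross pairs share units, so the normal CI is
anti-conservative and should be read as descriptive).  A unit with no
canopy-capable stems contributes similarity 0.

## Ordination

NMDS minimizes Kruskal stress-1, √(Σ(d̂ − d)²/Σd²), by SMACOF-style
majorization with the monotone regression re-solved each iteration
(isotonic regression on the dissimilarity order; primary tie treatment —
ties are pre-sorted by current configuration distance, leaving their fitted
values unordered).  Start 0 is the classical-scaling solution, so perfectly
embeddable inputs converge at machine precision immediately; remaining
starts are random (default 20).  Convergence is declared when the two
lowest-stress starts agree to Procrustes RMSE < 10⁻⁴ — like its R
analogues, the fit frequently reports non-convergence on noisy data even
when the best solution is stable, and the diagnostic is reported rather
than enforced.  The best configuration is centered, rotated to principal
axes (axis 1 = maximal variance) with a deterministic sign convention, and
can be re-oriented so axis 1 correlates positively with site age.
Dimension choice follows a scree rule (smallest k ≤ 4 with stress < 0.10),
overridable.  The frequent-species sensitivity analysis reports |r| of
axis-1 scores between full and thresholded fits, since axis sign is
arbitrary; squared-correlation readings are |r|².

## Permutational statistics

All permutation p-values use the add-one convention
p = (1 + #{perm ≥ obs})/(1 + N) and are exactly reproducible under a seed;
999 permutations is the default.  Mantel uses Pearson correlation of the
off-diagonal entries with simultaneous row/column permutation, one-sided by
default; n! enumeration is available for n ≤ ~7.  The correlogram tests
each Sturges distance class against its membership indicator, flips the
sign so positive r means "nearby units are similar", and applies
progressive Holm correction (class k corrected among the first k classes);
uncorrected p is also reported.  PERMANOVA is computed from the
Gower-centered matrix G = −½ J D² J and a design hat matrix H as
pseudo-F = (tr(HGH)/df_m)/(tr((I−H)G(I−H))/df_e), which coincides with the
classical pair-sum formulation for a categorical factor (and with one-way
ANOVA exactly when D is Euclidean distance of 1-D data).  Besides the
categorical coding (df = a − 1), a linear-contrast coding of ordered
classes gives a single-df test — both are exposed because published
single-df reports for three ordered classes are consistent with the latter;
categorical is the default.  Exhaustive enumeration runs over distinct
label-to-unit assignments.

## Succession regressions

Three two-parameter families: linear (OLS), power and exponential
(scipy `curve_fit`, initialized from log-space linear fits; a pure log-log
mode exists for comparison).  R² is always 1 − SSE/SST on the response
scale so families are comparable; significance is the F-test of the
two-parameter fit against the intercept-only model (df 1, n − 2).  Model
selection takes the highest-R² family among those with p ≤ 0.05 and
returns an explicit "ns" marker otherwise.  Because three correlated tests
are screened, the family-wise rejection rate on pure noise is somewhat
above the per-test 5% (the suite measures ≈ 15%); treat the selection as
descriptive, not as a calibrated test.  Power fits exclude zero responses
(with a logged count) rather than offsetting them, and require x > 0.

## Landscape frequencies and effective diversity

F₁ and F₅% are plot-level percentages over stems ≥ 1 cm of all life forms;
the ≥ 5% dominance boundary is inclusive, and the denominator is all such
stems in the plot (a trees-only denominator is a flag).  Rank-frequency
curves sort by descending F₁ (alphabetical tie-break) and are summarized by
the OLS slope of log₁₀F₁ on rank from the end of the top decile of nonzero
ranks through the last nonzero rank.  The log scale is deliberate: when
occupancy rises across the whole pool during succession, a raw-F₁ slope
steepens mechanically even as the curve flattens in the meaningful sense;
the log-scale decay rate expresses the flattening directly.

The RST machinery classifies species into maximum-DBH classes with
mid-values 3, 7.5, 15, 30, 60 cm; the open >80 class has no mid and uses
120 cm (1.5 × its lower bound, configurable) — at RST 30% this puts the
qualifying bar for emergent species at 36 cm.  An expert class label always
overrides an observed maximum; species with neither are excluded from RST
analyses with a logged count.  Only trees and shrubs enter (lianas and
palms excluded); seedlings carry no diameter and can never qualify, but do
count toward class species totals by default (excludable).  The rarity
variant requires qualifying stems in ≥ 2 distinct plots.  Percentage
reductions are reported to the integer.

## Pipeline and reproducibility

The pipeline runs stages in a fixed order from one YAML-able config; every
stochastic stage consumes an explicit seed, outputs are write-once, and a
manifest records a SHA-256 hash per file, so reruns with identical config
and seeds reproduce the hashes.  `scripts/acceptance.py` re-derives every
reported number from scratch at run time from `--seed`; the permutation
calibration stage there uses 100 null replicates at 199 permutations to
keep the full script in the tens of seconds, while the test suite runs the
heavier 200 × 999 calibration.

## Known limitations

* The chronosequence logic itself (space-for-time substitution) is outside
  the package's scope; nothing here corrects for site-history confounding.
* Normal-theory CIs over non-independent unit pairs (seedling divergence)
  are descriptive.
* The NMDS convergence diagnostic compares only the two best starts.
* Multi-factor PERMANOVA designs, partial Mantel, dispersion tests,
  coverage-based rarefaction and asymptotic richness estimators are
  deliberately not implemented.
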