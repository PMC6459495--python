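# Methods

This note records the models, conventions and numerical choices behind
`ecophylo`, in the order the pipeline applies them.

## Synthetic studies

The generator emulates a paired-parcel bait survey of a forest–grassland
ecotone system. The default design has 3 physiographic regions × 3 sites,
2 ecotones per site except one site with a single ecotone (17 ecotones),
one forest and one grassland parcel per ecotone (34 parcels), 14 baits per
parcel, and a pool of 85 species in 23 genera with Zipf-skewed genus sizes.

Occurrence counts are Binomial over baits — the sampling unit is the parcel
and the count is the number of occupied baits, matching the frequency-matrix
convention of bait surveys — with a per-species logistic occupancy model:

    occ[s, p] ~ Binomial(14, logistic(α_s + habitat + covariates + spatial))

* **Baseline** α_s ~ Normal(−5.5, 1.3). These values were fixed by matching
  Monte-Carlo summaries of the generator to what a real survey of this
  design reports: ~70–80 of 85 species detected, roughly half of the
  detected species seen in only one habitat, a handful of singletons, and
  a most-frequent species on ~60–70 of the 476 baits.
* **Habitat structure.** A fraction of species (default 0.5) are habitat
  specialists receiving ±half the habitat effect logit (default 3) in
  their preferred/avoided habitat. Specialists are assigned at random, or —
  for planting a lineage–habitat association — clade-wise: the species of
  the shallowest backbone clade holding at least half the target count all
  prefer forest and share a common baseline logit (−5.0). The shared
  moderate baseline matters: the taxa-shuffle test detects a lineage signal
  through *turnover* of intermediate-occupancy clade members among parcels,
  not through a few ubiquitous species.
* **Covariates.** Forest parcel temperature ~ Normal(24.8 °C, 2.0),
  grassland ~ Normal(29.9 °C, 2.0) (the two habitats' reported means);
  litter depth and canopy openness in forests; herbaceous vegetation height
  (cm) and shrub/treelet densities in grasslands. Air moisture is generated
  strongly collinear with temperature so the local VIF screen has a genuine
  removal target. Default planted slopes on the occupancy logit:
  +0.1 per °C (forests), −0.02 per cm vegetation height and +0.15 per
  treelet-density unit (grasslands). Regional (site-level) covariates form
  a collinear block — a latent temperature gradient measured as annual mean
  temperature, with minimum temperature of the coldest month and altitude
  derived from it — so the regional VIF ≤ 3 screen removes the hub
  variables, as in real WorldClim-style predictor sets.
* **Space.** Each species' regional log-odds receive a Gaussian random
  field over site coordinates with exponential covariance
  (sd 1.0, range 200 km), producing spatially autocorrelated composition
  among regions.

Setting every effect to zero (`EffectSpec.null()`) gives exchangeable
parcels — the basis of all calibration tests.

What the generator does *not* emulate: bait monopolisation by behaviourally
dominant species, detection covariance with weather, within-parcel spatial
structure of baits, and abundance (counts are occupancy, not workers).
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under a clean occupancy model, not robustness to
those field realities.

## Trees

The genus backbone is ultrametric (default depth 140 Myr). Grafting
replaces each genus tip by its species: monotypic genera keep the tip
depth; larger genera become polytomies with zero-length branches so all
tips sit at the present, the genus stem keeping its backbone length.

Polytomies are resolved by **sequential uniform attachment**: congeners are
added one at a time to a branch chosen uniformly among the branches of the
growing genus clade *including its stem*, at a height uniform on that
branch's interval. For three congeners this yields each rooted shape with
probability exactly 1/3. The scheme is seed-controlled; ultrametricity is
preserved by construction. Note its consequence: within-genus divergence
times are uniform over the whole genus stem, so genera on long backbone
branches get deep internal structure.

Patristic distances are computed by a post-order merge (O(n²)) and verified
against path enumeration; for downstream similarity they are rescaled to
[0, 1] by the matrix maximum, which makes S = 1 − D well defined. Whether
to rescale before similarity conversion is a convention choice; the
unit-max convention is adopted and applied consistently, including inside
every taxa-shuffle rebuild (where the maximum is permutation-invariant).

## Diversity

"Simpson index" is the Gini–Simpson form 1 − Σpᵢ², which makes Rao's
quadratic entropy with constant distances proportional to it (the two
metrics are then the same family, occurrence-proportion weighted). Faith
PD is root-inclusive by default (a one-species unit has PD equal to its
root-to-tip distance); `include_root=False` gives the crown-only variant.
Ensemble means and SDs are taken across trees per unit; when all per-tree
values coincide the SD is set to exactly zero rather than left to
floating-point noise.

## Ordination and PERMANOVA

PCoA uses Gower double-centering and drops axes with eigenvalues below
1e-10; no negative-eigenvalue correction is applied and axis percentages
use the positive-eigenvalue sum. PERMANOVA is the classical one-way
decomposition of squared distances; p-values use free permutations with
the +1 rule, or exhaustive enumeration of distinct assignments for n ≤ 9.
Permutation statistics are computed batched (one-hot einsum), which keeps
9,999 permutations at n = 34 around a fifth of a second.

## PCPS

The multiplication orientation for the phylogeny-weighted composition is
**P** = **W Q**ᵀ with **Q** column-standardised, the unique orientation
under which each unit's total occurrence count is conserved (each species'
weight is redistributed over its phylogenetic neighbourhood). Dissimilarity
among rows of **P** is square-root Bray–Curtis, which avoids negative
eigenvalues. The factor test statistic is the PERMANOVA pseudo-F of the
factor on that dissimilarity; the null rebuilds **S**, **Q**, **P** after
each taxa shuffle with **W** untouched. Across an ensemble, every tree
shares one null-permutation substream so that identical trees provably give
identical p-values; the report carries per-tree p-values, the proportion
with p ≤ α, and the all-trees decision rule.

## Spatial analysis and variation partitioning

Coordinates are projected to kilometres (equirectangular) before PCNM by
default; the truncation threshold is the longest minimum-spanning-tree
edge, distances beyond it are replaced by four times the threshold, and
only positive-eigenvalue eigenvectors are kept (unit-normalised).

RDA is least squares on column-centred matrices; the response for
composition analyses is the Hellinger-transformed occurrence matrix after
removal of singletons (species with exactly one occurrence), with units
emptied by that removal dropped. Forward selection enters the candidate
with the highest partial F, testing it against permutations of the
*maximum* partial F over remaining candidates (reduced-model residual
permutation). This max-statistic null is deliberate: testing the best
candidate against its own marginal null would inflate the per-step
family-wise inclusion error to roughly 1 − (1 − α)^m; the max-F version
keeps it at α exactly, which the calibration suite verifies.

Variation partitioning reports adjusted-R² fractions
[a] = adjR²(all) − adjR²(spatial), [c] = adjR²(all) − adjR²(env),
[b] = adjR²(env) + adjR²(spatial) − adjR²(all), [d] = 1 − adjR²(all);
they sum to 1 by construction. [a] and [c] are tested by partial-RDA
permutation of reduced-model residuals, the unions by plain RDA
permutation; [b] is not independently testable. The exact identity
"[b] = 0 for orthogonal predictor sets" holds only on the unadjusted
scale, so the result object also carries `raw_fractions`. In the pipeline,
varpart uses the forward-selected variable subsets; if a set comes back
empty, the top-F candidate stands in (flagged in the report) so the
partition stays defined at n = 9 sites.

## Mixed models and AICc

All fits are maximum likelihood, not REML, because candidates differ in
fixed effects and are AICc-compared. Gaussian models use statsmodels
MixedLM (best optimum across LBFGS/BFGS and Powell; a closed-form OLS fit
at the σ²_site = 0 boundary serves as fallback and floor, flagged
`boundary`). The Poisson random-intercept marginal likelihood is integrated
by 31-node Gauss–Hermite quadrature over the site effect and maximised with
L-BFGS-B (σ ≥ 0 bound); fixed-effect covariances come from the numerical
observed information. Parameter counts: p + 2 (Gaussian), p + 1 (Poisson).

Candidate sets: null, singles, additive pairs, interaction pairs
(a + b + a:b), full additive model, deduplicated. AICc uses the standard
small-sample correction; models with n ≤ k + 1 are flagged unrankable.
Conditional R² is (var_fixed + σ²_site)/(var_fixed + σ²_site + σ²_resid)
for Gaussian; for Poisson the observation-level variance is the trigamma
function at the expected rate (lognormal approximation behind a flag).

Factor comparisons use the likelihood-ratio χ² of the factor model against
the null and Tukey-style pairwise contrasts: z statistics from the
fixed-effect covariance with a single-step (max-|z|) adjustment evaluated
by seeded Monte Carlo on the joint normal of the contrasts.

At the regional scale, diversity responses are the mean of each site's
ecotone values (ecotone = pooled forest + grassland parcels) and
composition uses occurrences summed per site. With nine site-level values
and site as the grouping factor the random intercept is confounded with
the residual; fits then typically sit at the σ²_site = 0 boundary and are
flagged as such — a known limitation of that design, reproduced
deliberately.

## Seeds and problem sizes

Every stage draws from a named substream of one master seed
(`SeedSequence` with a CRC32 spawn key), so reports are byte-identical
across reruns and no stage shares a stream with the data feeding it — the
calibration suite demonstrated that reusing one integer for both the study
and the permutation stream visibly distorts permutation p-values.

Workflow defaults follow the survey conventions this pipeline implements:
1000-tree ensembles, 9,999 Adonis/taxa-shuffle permutations, 999 RDA
permutations, α = 0.05, VIF threshold 3. Simulation-based tests and the
acceptance script run scaled problem sizes chosen as the package's own
test-design choice (e.g. 100–1000-tree ensembles, 199–999 permutations,
50–200 replicate studies); each test states its sizes, and permutation
counts only affect the resolution, not the validity, of Monte-Carlo
p-values.

## Known limitations

* The sequential-attachment resolution is one of several defensible
  polytomy-resolution schemes; it is uniform over shapes for three
  congeners but not over labelled topologies for larger genera.
* PCoA applies no Lingoes/Cailliez correction; with square-root
  Bray–Curtis this has not produced material negative eigenvalues.
* The Poisson GLMM uses non-adaptive quadrature; for very large counts or
  site variances the 31-node rule would lose accuracy.
* LR factor tests rely on the χ² asymptotics; at n = 34 they are close to
  nominal for well-behaved responses but can run a few points hot for
  skewed ones.
* Free permutations are used at both scales (no within-site restriction);
  a strata-restricted scheme is a natural extension hook.
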