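# Methods

## Reaction-norm models

Each trait in each species is modeled as a fixed-effects linear regression on
harvest cohort `H` (categorical), genotype `G` (categorical, treatment-coded
against the lexicographically first level), and three environmental
predictors of final gravimetric soil moisture `E`: the raw value, its square
`E²`, and a df=2 natural cubic spline `s(E)`. Genotype is deliberately a
fixed effect: with a handful of inbred lines per species there is too little
replication at the genotype level for random-regression approaches, and AIC
comparison across models with different environmental bases requires a
common likelihood.

`E²` and `s(E)` are main-effect terms in their own right: an interaction
such as `G:s(E)` requires only `G` and `s(E)` to be present, and no
environmental term requires `E`. This mirrors formula-term semantics in
standard linear-model software and is what allows final models to carry a
nonlinear environmental predictor without the (always-aliased) linear one.

### Spline basis

The natural cubic spline uses boundary knots at the per-species observed
moisture extremes and one interior knot at the median, frozen into the
fitted model so grid prediction reuses the fitting basis. The basis is the
cubic B-spline design projected onto the null space of the two
second-derivative-at-boundary constraints, with explicit first-order Taylor
extension outside the boundary knots (natural splines are linear there, so
the extension is exact, and evaluation at 30% moisture is well defined even
when a species' observed minimum lies above 30%). Quadratic terms
extrapolate as fitted. Together with the intercept the basis spans the full
natural-spline space, which contains every linear function — hence the full
design matrix is rank-deficient by construction.

### Least squares and AIC

Fits use QR with column pivoting; rank is determined from the R-diagonal at
tolerance `|R₀₀|·max(n,p)·ε`. Aliased columns are flagged and contribute
zero to predictions, a basis-independent choice (fitted values are unique).
The selection criterion is `AIC = n·ln(RSS/n) + 2·rank`: the Gaussian
constant is identical across candidates and dropped, and the penalty counts
the rank, not the column count, so aliasing never buys a model anything.
A perfect fit (RSS below `1e-14·(‖y‖²+1)`) maps to −∞ and such models are
compared by rank.

### Stepwise search

Selection starts from the full 8-term model and considers single-term
deletions and additions (scope limited to the full model's terms) that
respect marginality, applying the best strictly-improving move until none
exists, with a 50-step safeguard. Two deterministic refinements, both
validated against R's `MASS::stepAIC` on shared datasets (the test suite
regenerates this comparison through `Rscript`):

* a term whose columns are wholly collinear with the rest of the current
  model (zero effective df, e.g. `E` next to `s(E)`) is deleted outright
  before AIC moves are weighed, last-in-term-order first — the reference
  implementation does exactly this, and the *order* of these removals
  changes which local optimum the greedy search reaches;
* remaining exact ties (|ΔAIC| ≤ 1e-10) prefer deletion over addition and
  then the fixed term order `H, G, E, E², s(E), G:E, G:E², G:s(E)`; the
  reference resolves such ties by floating-point jitter, which we replace
  with an explicit rule.

Stepwise AIC is known to be liberal: under a pure intercept+genotype truth
with 600 observations and five genotypes, roughly 35–50% of replicates
retain at least one (spurious) environmental term, a family-wise consequence
of ~6 correlated candidate terms each surviving with probability
`P(χ²_df > 2·df)` ≈ 9–16%. This is a property of the method, reproduced
identically by the reference implementation, and should be kept in mind when
reading single-dataset term tables. Recovery of genuine signal is excellent:
with between-genotype curvature spread twice the residual sd, a nonlinear
environmental term plus a GxE term is selected in ≈100% of replicates.

## Grid predictions and genetic correlations

Genotype means are evaluated on 20 evenly spaced levels from 30% to 100%
gravimetric moisture. Harvest cohort is marginalized by averaging
predictions over all cohort levels with equal weight — invariant to the
choice of reference level, unlike predicting at a fixed cohort.

Pearson correlations between genotype means are computed per trait pair per
level within species. Traits whose final model contains no genotype term
(neither `G` nor any `G:·` interaction) have identical predictions for all
genotypes; their "genetic" correlations are undefined and the pairs are
omitted. Zero-variance cases yield a flagged missing value, never 0.

## Multivariate plasticity

Within each species, predicted genotype means are z-scored per trait over
the pooled genotype × level rows (sd with divisor n−1). Pooling within
species preserves cross-level comparability; the package deliberately does
not scale per level (a documented consequence: scaling then subsetting is
not subsetting then scaling). Traits without genotype terms are retained by
default — they still move with the environment and contribute to each
genotype's path — behind a flag; traits whose model kept no terms at all are
constant, cannot be z-scored, and leave the trait space.

`ΔT_{g,i}` is the Euclidean distance between the scaled trait vectors of
genotype `g` at consecutive levels `m_i`, `m_{i+1}` (19 intervals). Species
are compared per interval with Welch's unequal-variance t-test at α = 0.05
and no multiplicity correction; with five genotypes per species these tests
are indicative, not powerful. The trait-space PCA is a centered SVD with
sample-covariance eigenvalues; component signs are fixed by making each
component's largest-magnitude loading positive.

## Constraint statistics

At each grid level, each trait's genotype means are divided by their mean
across genotypes at that level (mean standardization; the per-level G matrix
is self-contained — a grand-mean option exists). Division is by the signed
mean as is conventional: a negative-mean trait such as δ¹³C flips the sign
of its standardized deviations, so covariances involving it change sign
relative to the raw scale; an `abs_mean` option disables this. Traits whose
mean sits within `1e-8·sd` of zero are dropped with a warning — mean
standardization is meaningless there. **G** is the sample covariance
(divisor n−1) across genotypes, restricted to traits with genotype terms in
the selected models.

Eigenvalues come from a symmetric decomposition, sorted descending, with
negatives within `−1e-10·λ₁` clamped to zero. `nD = Σλ/λ₁ ∈ [1, n]`,
`e_max = √λ₁`, `v_T = Σλ = tr(G)` (checked as a conservation identity at
every level), `prop1 = λ₁/Σλ = 1/nD`. With genotype means near zero (e.g.
shoot mass in very dry soil), mean standardization inflates that trait's
standardized variance — large dry-end `v_T` values partly reflect this
known property of the statistic.

## Synthetic dry-down generator

The generator is the package's model of the experiment it analyzes, with
every stochastic element driven by one seed (stage streams spawned
deterministically from it).

**Design.** Two species × 5 genotypes × 60 plants; watering treatments 0, 4,
8, 12, 16, 20 ml/day for 14 days, balanced over five harvest cohorts; pots
start at field capacity (200 g plant-available water over a 400 g dry mass).

**Moisture dynamics.** Daily loss is
`rate·W·u^p` with `u` the plant-available fraction above a residual
bound-water fraction (0.28 of capacity) and `p = 0.5`; a multiplicative
`N(0, 0.2)` daily perturbation is the noise source. At field capacity the
loss equals `rate·W` = 20 ml, so the wettest treatment is pinned at 100%;
the unwatered treatment decays to just under 30%; and the sublinear exponent
keeps drying fast until the soil is nearly dry, crowding intermediate
treatments toward the dry end. This yields the characteristic dry-skewed
pooled distribution of final moisture (noise-free treatment finals ≈ 28, 36,
50, 65, 82, 100%). The gravimetric percentage is
`(mass_d − mass_dry)/(mass_max − mass_dry)·100` by default; an `as_printed`
flag offers the variant that leaves the dry mass in the numerator (which
exceeds 100% by a constant offset) for compatibility with data recorded
under that convention.

**Reaction norms.** Each species × trait has a quadratic mean response
through three anchors (values at 30%, 65%, 100% moisture) chosen to echo
typical dry-down physiology: RWC ≈ 0.87 at 30% rising to ≈ 0.98 when wet,
SLA peaking at intermediate moisture in the annual, green area and biomass
increasing with moisture, root:shoot rising under drought, δ¹³C least
negative (highest WUE) in dry soil. Genotype effects are a shared per-
genotype "quality" factor plus a 10% idiosyncratic part, scaled by per-trait
CVs (16% for size-like traits down to 1–2% for composition traits), so the
genetic covariance concentrates on one axis (nD near 1, first eigenvector
typically >90% of variance). Genotype-effect amplitude varies linearly with
moisture in opposite directions for the two species (annual: largest when
dry; perennial: largest when wet), reproducing the contrasting
cryptic-variation pattern expected from their life histories. Flagged traits
add genotype-specific quadratic curvature (GxE, correlated 0.9 with the
quality factor); a few traits per species have no genotype signal at all, so
some selected models legitimately omit `G`. Cohort effects are small
additive age offsets; residual noise is 5% of trait scale. Raw-measurement
traits (RWC, SLA, root:shoot, biomass, C:N) also exist as derivation rules
from raw harvest sheets with undefined ratios flagged missing.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: measurement error correlated across traits
within a plant, genotype-specific phenology or germination, spatial
greenhouse effects, image-analysis artifacts in green area, and truths
outside the quadratic/truncated-cubic families (real reaction norms may be
steeper-than-cubic threshold responses). The split destructive harvest is
emulated (each plant carries either the biomass/chemistry panel or SLA+RWC),
balanced so harvest group is not confounded with treatment.

## Problem sizes and determinism

Unit and acceptance tests run on synthetic experiments of 120–600 plants per
species and simulation studies of 100 replicates per arm — sizes at which
every statistic here is stable while the full suite completes in well under
a minute of compute. All tests and the acceptance script are seeded;
pipeline runs with the same seed and config are byte-identical (the manifest
records SHA-256 per artifact).

## Known limitations

* Stepwise AIC's liberality (above): term tables from single datasets
  overstate environmental structure at roughly the measured family-wise
  rates; the pipeline reports selection traces so the margin of each choice
  is auditable.
* The greedy search can stop in a local AIC optimum; which optimum depends
  on the zero-df removal order (matched to the reference implementation).
* With five genotypes, correlations and G matrices are 5-point statistics:
  `nD` is bounded by 5 in practice and all constraint statistics carry large
  sampling error; the package reports point values, as is standard, and
  leaves uncertainty quantification to the user's resampling.
* Mean standardization is unstable for traits whose genotype means approach
  zero anywhere on the grid; such traits are dropped per level with a
  warning rather than silently inflating `v_T`.
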