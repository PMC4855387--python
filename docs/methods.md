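# Methods

`reefcomposite` implements a community-level ("seascape genetics") analysis
of genetic diversity for many co-distributed species sampled across an
island chain, together with the simulation machinery needed to validate
every step against known ground truth. This note records the models, the
defaults and why they were chosen, the numerical decisions, and the known
limitations.

## Rarefied allelic richness

Allelic richness (AR) is the expected number of distinct alleles in a
standardized subsample of `g` gene copies drawn without replacement from an
observed sample of `N` copies with allele counts `N_i`:

    AR_g = sum_i [ 1 - C(N - N_i, g) / C(N, g) ]

Each term is the probability that allele `i` appears at least once in the
subsample. The binomial ratio is evaluated as the telescoping product
`prod_{j<g} (N - N_i - j)/(N - j)`, which is exact in floating point for the
sample sizes that occur here and never overflows; no Monte-Carlo
approximation is involved. When `N = g` the statistic equals the observed
distinct-allele count; it is monotone non-decreasing in `g`.

Defaults: `g = 6` gene copies for haploid (mtDNA) loci — the "alleles per
six individuals" reporting unit — and `g = 12` for diploid loci (six
individuals' worth of copies). Whether diploid data should be standardized
to six individuals or six copies is a genuine ambiguity; both depths are
plain arguments. Multi-locus species values are the unweighted mean of
per-locus AR over loci with `N >= g`; loci are weighted equally because no
principled weighting across non-homologous markers exists at this level.

Inclusion rules mirror the sampling design the package targets: a
species-island sample needs at least 6 individuals; a species must remain on
at least 2 islands; an optional strict filter (e.g. 10) implements the
sensitivity variant that discards the 6–9-individual tail. Specimens are
counted as individuals; rarefaction feasibility is checked in gene copies
per locus, so missing genotypes reduce copies without discarding the
individual elsewhere.

## Composite (multi-species) AR

The community statistic is, per island, the mean AR of `k = 12` species
drawn without replacement from those with an AR value there, repeated
`n_resamples = 500` times; the composite is the mean of the draw means and
`mc_sd` their standard deviation. Islands with fewer than `k` species are
excluded rather than imputed. Because the expectation of every
without-replacement subset mean equals the plain mean of the available
species, the composite is an unbiased, variance-standardized version of that
mean; the resampling exists to standardize the species count across islands,
not to change the estimand.

RNG design: each island gets its own stream derived from the master seed and
a CRC of the island name, so adding or removing an island never perturbs the
others, and a fixed seed reproduces the output bit-for-bit.

## Congruence and its calibration

A species's congruence is the Pearson correlation of its island AR vector
with the composite vector over jointly defined islands (species qualify at
>= 6 islands; species-by-driver correlations use >= 5). The community-level
tendency is tested with a one-sample, one-sided t-test of mean r > 0 with
df = (number of tested species) - 1.

Two properties of this test are worth stating plainly:

* **Self-correlation bias.** With the all-species composite (the default,
  matching the original analysis design), the focal species contributes to
  the pattern it is correlated against; under a fully null community the
  expected r is about `1/sqrt(n_species)` (~0.15 for 47 species), not 0. The
  `leave_one_out` mode removes this bias by correlating against the mean AR
  of the remaining species — the exact limit of the resampled composite
  without the focal species, used instead of re-running the Monte Carlo
  because it has the same expectation and no added jitter.
* **Residual anticonservatism.** Even leave-one-out correlations are not
  independent across species: species s appears inside the composite used
  for species s', and vice versa, so `cov(r_s, r_s') ~ Var(r)/(n_species-1)`.
  For ~47 tested species this roughly doubles the variance of the mean r
  relative to the independence assumption behind the t-test, and the
  realized type-I rate at nominal 5% is ~10% (measured at 1000 replicates of
  the null generator, and reproduced by an abstract i.i.d. mock independent
  of the generator). The t-test is kept as the community congruence
  statistic because it is the field's standard; its p-values under a fully
  null community should be read with this inflation in mind. Power against
  a genuinely shared driver is high (>= 0.8 at the generator's default
  effect size, measured at 200 replicates).

## Seascape model selection

Exhaustive OLS model selection relates the per-island composite to seascape
predictors: every subset of 1–3 predictors plus the intercept-only
reference, ranked by small-sample AICc

    AICc = n ln(RSS/n) + n ln(2 pi) + n + 2K + 2K(K+1)/(n - K - 1)

with `K` counting the regression coefficients (including the intercept)
*plus* the residual variance — the standard ML bookkeeping, consistent with
K = 3 for a one-predictor Gaussian model. The top set is ΔAICc < 2; Akaike
weights `w_i = exp(-Δ_i/2)/Σ exp(-Δ_j/2)` are normalized over the predictor
subsets, with the intercept-only model reported as a reference row (its
ΔAICc from the best model is the "is anything going on at all" diagnostic).
Ties are broken deterministically (AICc, then fewer terms, then name).
Models are limited to three terms because the composite is observed at ~13
islands. Degenerate candidates (perfect fits, rank deficiency, n too small
for the correction) are skipped with recorded reasons. An optional sign
filter drops top-set models whose coefficient signs oppose a supplied
hypothesis map; it is off by default.

The species-level counterpart fits the same candidate sets as linear mixed
models on the long table of species-by-marker × island AR records with a
random intercept per species-by-marker group, estimated by maximum
likelihood (not REML — REML deviances are not comparable across fixed-effect
sets). `K` adds the group variance on top of the OLS bookkeeping. Singular
fits (group variance -> 0) are retained and flagged; in that limit the fixed
effects coincide with pooled OLS, which is tested.

Predictors are pre-screened for colinearity: while any pair has |r| >= 0.7,
the member with the larger mean absolute correlation to the rest is dropped
(greedy), and the full pairwise matrix is always emitted. The retained
default set (habitat area, LGM loss, coral cover, CCA cover, thermal
stress) stays below pairwise |r| ~ 0.5 under the generator defaults.
The LGM habitat-loss predictor is `1 - area_LGM/area_present`, clamped to
[0, 1]; the margins-vs-centre test is an OLS of the composite on latitude
and latitude² with the overall-F p-value.

Trait models reuse the OLS enumeration with species as rows and the
correlation profile (species × driver Pearson r) as responses; a partial
mode residualizes the response on sampling covariates (islands sampled,
marker type, total marker diversity) first.

## Ordination and spatial screening

RDA projects the column-centred species × driver correlation matrix onto
the standardized trait matrix; the constrained proportion is
`trace(Yhat'Yhat)/trace(Y'Y)` and the axes are the SVD of the fitted
values. Inference is by unrestricted row permutation of the trait matrix
with an add-one p-value (999 permutations by default). Partial RDA
residualizes both response and predictors on covariates and reports the
proportion of the covariate-residual variance. The computation is checked
against an explicit hat-matrix oracle and against vegan's `rda`.

Moran's I uses inverse great-circle-distance weights by default (zero
diagonal), with a chain-adjacency mode for small-scale checks and optional
row standardization (ape's convention); the tail is configurable and
defaults to "greater" (positive autocorrelation is the concern). Inference
is again permutational with an add-one p. Weight choices are recorded in the
output because no single convention is canonical.

## Stepping-stone simulator

A forward-time haploid Wright–Fisher chain with per-deme sizes `N_i`,
per-copy infinite-alleles mutation `mu`, and migration `m` split equally
between adjacent demes; edge demes send the full `m` to their single
neighbour, conserving emigrant mass — edge handling is recorded in the
output metadata because edge diversity is exactly the quantity of interest.
Forward WF was chosen over a coalescent because its stationary sample obeys
the Ewens sampling formula (theta = 2 N mu per deme in the panmictic limit),
giving an exact external check:

    E[K_n] = sum_{i=0}^{n-1} theta / (theta + i)

The Chinese-restaurant sampler draws from this equilibrium directly and ties
the simulator, the rarefaction code and the data generator into one closed
verification loop. Burn-in defaults to `10 * max(N_i)` generations (with an
optional plateau check on the last two windows); populations start maximally
diverse so the approach to equilibrium is from above. Replicates use
independent spawned streams, so the result for replicate r does not depend
on how many replicates follow. Demes share one stream within a replicate;
consequently label-permutation symmetry holds distributionally, not
bitwise.

The margin-diversity experiment uses 15 demes with a smooth U-shaped size
profile (~3x larger at both ends, matching the island chain's habitat-area
contrast), m = 0.05, mu = 5e-3, 100 replicates, and compares mean sampled
AR at the two margins against the three smallest central demes with a
one-sided paired t-test. These sizes give a clearly resolved contrast at
minute-scale runtimes; the direction, not the magnitude, is the claim under
test.

## Synthetic data generator

The generator emulates the study inputs with known truth. The archipelago
is a 13-island chain whose habitat areas follow a U-shaped log-area profile
spanning 6.6–470 km² (maxima at the margins); other predictors are Gaussian
copula draws correlated with transformed area at configurable r (default
max ~0.5) and mapped linearly into natural ranges; potential immigration is
a centre-peaked curve (the stepping-stone connectivity expectation); region
labels split the chain into a 6-island MHI block and an NWHI remainder.

The community layer draws 47 species with trait vectors (fish/invertebrate,
endemism, log PLD, body size, depth, habitat specialization, herbivory, and
differentiation statistics that decline with a latent dispersal ability),
island occupancy (baseline 0.78, with opposing endemic/non-endemic
latitudinal gradients in the `endemic_flip` scenario), and per-cell sample
sizes averaging ~32 individuals with a 10% tail at 6–9 — so the inclusion
and composite-exclusion rules are actually exercised.

Genetic mode `crp` (default) draws allele counts from the Ewens sampling
formula with

    log theta_si = log c_s + beta_area * z_area(i) + e_i + e_si

where `c_s` is a lognormal species level (median 2.2, chosen so composite
AR lands in the ~3–4 alleles-per-6-copies range), `beta_area` the causal
habitat effect, `e_i` an island-level noise shared across species and
`e_si` cell noise. Because `E[AR]` is then known analytically, every
downstream stage has a closed-form oracle. Mode `structured` instead runs
the stepping-stone simulator per species with habitat-scaled deme sizes and
a species-specific migration rate.

Preset calibration: in `habitat_driver`, `beta_area = 0.45` per SD of
transformed area with island noise SD 0.4 makes the regression of composite
AR on habitat area land at realized r² ~ 0.5–0.6 across seeds — the
signal-to-noise regime the analysis is meant to operate in; `null` sets all
island-level effects to zero (cells i.i.d. across islands); presets are
versioned configs, and the latent truth (per-cell theta, causal effects) is
a first-class output so tests never reach into generator internals.

What the generator does not emulate: sequence-level mutation spectra
(alleles are labels), oceanographic realism in the immigration column,
spatially autocorrelated environmental noise, and species interactions.
Passing recovery tests therefore show that the pipeline recovers the drivers
it was built to recover under a faithful sampling design — not that real
reef data satisfy the generative assumptions.

## Pipeline and reproducibility

`run_pipeline` executes ingest/generate → inclusion filters → rarefaction →
composite → congruence + driver correlations → colinearity screen → OLS and
mixed model selection (archipelago-wide and per region) → quadratic
latitude fit → trait models → RDA → Moran's I, writing plain CSV/JSON at
each stage plus a manifest with config hash, seeds, input digests, per-stage
timings and every exclusion with a machine-readable reason. One master seed
drives all stages; reruns are bit-identical. `make_report` only reads
completed stage outputs (recomputing nothing) and renders the model tables
and the standard figures.

## Problem sizes used in validation

The validation experiments run at: 500 random count vectors for the
rarefaction-enumeration check; 20,000 equilibrium draws per theta for the
Ewens agreement; 600 single-deme replicates for the panmictic limit; 100
chain replicates for the margin contrast; 200 replicates each for driver
recovery and congruence power; 1000 for null calibration. These sizes put
the Monte-Carlo error well below the tolerances being asserted while
keeping the full suite at minutes on one core.
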