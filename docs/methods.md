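# Methods

## Model overview

`splitdrive` couples three layers, applied in this order every simulated
day, per patch:

1. **Egg laying.**  Each mated-female class (own genotype × stored mate
   genotype) lays `Poisson(β · f(own) · count)` eggs, where `f` is the
   female fecundity multiplier; offspring genotypes are multinomial draws
   from the inheritance-cube row of the pair.
2. **Survival.**  Binomial thinning of every cohort: eggs/larvae/pupae at
   the shared daily juvenile mortality μ_J, larvae additionally at the
   density-dependent survival `(α/(α+L))^(1/tL)` evaluated at the total
   larval census *before* thinning, and adults at μ_ad inflated by the
   genotype's mortality multiplier.
3. **Advancement.**  Survivors age one day; final-day eggs become larvae,
   larvae become pupae, and final-day pupae emerge as adults with
   independent fair-coin sex assignment.
4. **Mating.**  Newly emerged females (plus any previously unmated ones)
   draw a mate genotype from the current adult-male genotype frequencies
   and keep it for life.  If no males are present they wait, unmated and
   non-reproducing, and retry daily.

After the per-patch step, adults (males, unmated females, and mated
females carrying their stored mate genotype) migrate between patches by
per-individual multinomial draws, and scheduled releases are added to the
target patch's adult pool — released males therefore first compete for
matings on the following day.  The paper-facing event order within a day
(lay → survive → advance → mate → migrate → release) is a modelling choice;
it is fixed, documented here, and identical in the stochastic and
deterministic code paths.

## Inheritance

Genotypes are unordered diploid allele pairs per locus, canonically sorted,
giving 30 genotypes for the split system (3 Cas9 × 10 target), 10 for the
linked system and 3 for the refractory comparator.  Gametogenesis in a
`G/w` (or `H/w`) germline with Cas9 available cleaves the `w` chromatid
with probability `c_sex`; given cleavage, HDR copies the drive allele with
probability `h_sex`, else the chromatid becomes `r1` with probability ρ₁
and `r2` otherwise.  Everything else is Mendelian, and the two split-drive
loci assort independently.  The cube is the outer product of maternal and
paternal gamete distributions, optionally followed by a maternal-deposition
transform (each offspring `w` allele converted with probability
`deposition_rate`, split ρ₁ : 1−ρ₁ between `r1`/`r2`) applied only to rows
whose mother carries *both* Cas9 and a gRNA source — the deposited
ribonucleoprotein needs the guide, so a Cas9-only mother deposits nothing.

Two readings of the measured "HDR frequency" are supported.  The default
takes `h` as P(HDR | cleavage) per chromatid, so the effective female
transmission is ½ + ½·c·h = 0.9025 at the default rates;
`hdr_is_transmission=True` instead takes the number as the effective
transmission itself.  The default follows the parameter statement as
written; the measured G₂ transmission (80.5%) corresponds to the second
reading, and the tension between the two cannot be resolved from the
available description.

### Fitness

* Female fecundity is multiplied by `(1 − 0.078)` per Cas9-bearing allele
  (`C`, or `H` in the linked system).  Males pay no fecundity cost.
* A 10% reduction in mean adult lifespan applies to the homozygous cargo
  cost class and is mapped, under exponential adult survival, to a
  mortality-rate multiplier of 1/0.9.  The class defaults to genotypes
  whose target-locus pair is drawn entirely from {cargo, r2} — both
  alleles ablate the target gene, and `r2` is out-of-frame and costly but
  of unstated magnitude, so it is pooled with the cargo homozygote.  This
  is configurable (`r2_shares_cost_class=False` restricts the class to
  cargo homozygotes proper); ensemble experiments show the headline
  metrics shift by only a few percentage points between the two readings.

## Demographic calibration

Juvenile daily mortality solves the generational balance
`(β/μ_ad) · (1−μ_J)^(tE+tL+tP) · ½ = R_m` by bisection (interval shrunk to
10⁻¹⁴; the balance residual is below 10⁻¹⁰).  At the wild-type fixed point
the density-dependent survival over the whole larval stage is exactly
1/R_m, which yields the density parameter in closed form,
`α = L_eq/(R_m − 1)`, with `L_eq` the equilibrium larval census implied by
β, μ_J and N_eq.  The closed form is verified in the tests by running the
deterministic recursion to stationarity (adult census within 0.1% of N_eq,
relative drift < 10⁻⁶ over 50 days).  The deterministic mode shares the
step code with the stochastic mode, replacing draws by expectations, and
serves as the large-population limit in the test suite.

Life-history defaults (β = 20 eggs/female/day; tE, tL, tP = 5, 6, 4 days;
μ_ad = 0.09/day; R_m = 1.096 per generation; N_eq = 10,000 adults) are
standard *Ae. aegypti* values for this modelling framework; every one is
overridable in the configuration.  The implied juvenile mortality is
μ_J ≈ 0.265/day and the mean generation time is 26 days, which is also the
compounding horizon used to convert the 1%-per-generation migration rate
to a daily probability (≈ 3.86×10⁻⁴/day).

## Metrics

The carrier fraction is computed over adult females (the panel convention):
females with at least one cargo allele divided by all adult females, NaN
when a patch has no females.  Allele frequencies are counted over all
adults (2N allele copies).  Headline metrics are computed on ensemble-mean
trajectories, with per-realization variants available.  The *window of
protection* is the number of days the mean carrier fraction stays strictly
above a threshold (default 80%); both the longest contiguous run (the
headline) and the total day count are reported.  The heatmap experiment
re-runs the ensemble over a grid of homozygote lifespan costs × numbers of
weekly releases, sharing the base seed across cells (common random
numbers) so that grid trends are not masked by sampling noise.

## Synthetic breeding experiments

The cross module forward-simulates replicate G₁/G₂ crosses from the same
inheritance cube: each replicate mother contributes a multinomial draw of
scored offspring, each offspring scored for the cargo marker, the Cas9
marker, and eye phenotype.  Eyes are white iff both target alleles are
pigmentation-null ({G, H, r2}); `r1` is in-frame and assumed to restore
pigment in all cases.  Mosaicism is phenomenological: offspring retaining
a cleavable `w` allele under Cas9 exposure (own machinery or maternal
carryover) are scored mosaic with a fixed probability, default 1.0,
matching the near-complete somatic mosaicism of the strongest Cas9 line.
The generator reproduces the sampling structure of the real experiments
(binomial transmission, replicate broods, maternal carryover) but not
brood-size variation, viability selection, scoring error, or
between-parent rate heterogeneity — parameter-recovery results therefore
bound estimator behaviour under ideal sampling only.

Estimators: transmission and mutant-phenotype rates are pooled proportions
with exact Clopper–Pearson intervals; super-Mendelian inheritance is
tested one-sided against 0.5 by an exact binomial test (default) or a
replicate-mean t-test.  (c, h) are jointly identifiable from a cross to a
marker-free pigmentation-null father (`+/+;r2/r2`): with t the cargo
fraction and W the white fraction, c = (2t−1) + 2(W−t)/(1−ρ₁) and
h = (2t−1)/c.  The deposition rate can be calibrated so that the expected
fraction of double-marker-negative offspring with white eyes matches an
observed value (0.31% by default); deposition is off in all release
scenarios.

## Numerical choices

* Cube rows are renormalised so each row sums to exactly 1.0 in floating
  point (residual pushed into the row's largest entry), keeping multinomial
  sampling safe; row-stochasticity is asserted at 10⁻¹².
* All randomness flows from a single `SeedSequence`; each realization
  spawns one child stream per patch plus one for migration, so identical
  (config, seed) pairs give bit-identical trajectories and an isolated
  patch evolves exactly as it would alone.
* Integer counts throughout the stochastic path (int64); the deterministic
  path is float64.
* Mate choice ties are broken by the multinomial draw itself; the
  degenerate no-male case routes females to a non-reproducing unmated pool.
* Releases of genotypes outside the system's genotype space, probabilities
  outside [0,1], and negative counts raise configuration/invariant errors
  with day context.

## Problem sizes

Release-scenario ensembles use 20 stochastic realizations of the full
5-year, two-patch, 10,000-adult scenario (the original analysis used 100;
20 keeps ensemble-mean sampling error on carrier fractions near one
percentage point).  Property tests run on smaller populations (400–2,000
adults) and shorter horizons, which is sufficient because the properties
checked (conservation, closure, reproducibility, distributional
agreement) are scale-free.  The heatmap monotonicity check uses a
2,000-adult single-patch population over three years.

## Known limitations

* The target gene is really sex-linked in *Ae. aegypti*; both loci are
  modelled as autosomal and unlinked, matching the original modelling
  treatment.  Sex-biased transmission of the cargo is therefore absent.
* Cleavage/HDR rates are identical for Cas9 heterozygotes and homozygotes,
  and between-individual rate heterogeneity is not modelled.
* The post-release persistence metrics are sensitive to the life-history
  values, for which only framework-standard defaults are available: under
  these defaults the acceptance script computes a release-patch carrier
  fraction of ~70% three years after the final release and a ~2-year
  window of protection, with confinement (neighbour-patch Cas9 peaking
  near 2%) and reversibility (monotone post-release Cas9 decline)
  reproduced.  Longer adult lifespans (fewer generations per year) would
  lengthen all persistence metrics proportionally.
* No seasonality, temperature forcing, larval instar substructure, or
  epidemiological layer; the model tracks genotypes, not disease
  incidence.
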