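# Methods

This note documents the model implemented in `canpros`, its assumptions,
the numerical choices, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Model structure

A man's prostate cancer hazard at integer age `t` is

    lambda(t | G, A, B) = lambda0(t) * RR_major(G, t, birth_year)
                          * exp( sigma(t) * (alpha*A + sqrt(1-alpha^2)*B) )

with `G` the joint genotype at four biallelic loci and `(A, B)` the two
polygenic sub-components. Ages are integer years with half-open intervals
`[a, a+1)`; a diagnosis "at age a" contributes the survival to `a` times the
probability of an event in that year, `exp(-H(a)) * (1 - exp(-lambda_a))`.

### Major loci

| locus  | effect | default frequency | default RR |
|--------|--------|------------------|------------|
| BRCA2  | dominant carrier, age-banded RR | 0.00102 | 9.0 / 6.6 / 4.5 / 2.8 for <55 / 55–64 / 65–74 / 75+ |
| BRCA1  | dominant carrier, age-banded RR | 0.00064 | 1.8 (<65), 1.0 (65+) |
| HOXB13 G84E | multiplicative per allele, birth-cohort RR | 0.00212 | 2.1 (born <1930), 3.6 (born ≥1930) |
| fourth gene | recessive homozygote (configurable) | 0.12 | 8.0 |

The polygenic-SD law (`sigma70 = 2.13`, relative rate `r = 0.989` per year
of age), the PGS-explained SD fraction (`alpha = 0.523`) and the test
sensitivities (0.83 BRCA2, 0.65 BRCA1, reflecting protein-truncating-variant
panels that miss some pathogenic classes; specificity is taken as perfect)
are the published estimates for this model family. The BRCA1/2 relative-risk
curves, the HOXB13 cohort RRs and the fourth-gene parameters are
*assumed external inputs*: the defaults are plausible values guided by the
published carrier-risk literature (declining BRCA2 RR with age of roughly
the published average magnitude; a weak BRCA1 effect concentrated below 65;
HOXB13 per-allele RRs near the published cohort-specific estimates; a rare
high-risk recessive component of the kind repeatedly suggested by
segregation analyses). They were fixed once, before any comparison with
published scenario outputs, and deliberately **not** back-solved from
published absolute-risk figures — doing so would make any agreement
circular. Consequently the package reproduces published scenario risks
closely where they are driven by the published polygenic parameters
(population, family-history and PGS-percentile scenarios) and only
qualitatively for BRCA2/HOXB13 carriers, whose exact fitted inputs are not
publicly printed. All of them are replaceable through the parameter YAML.

### Polygene discretisation

Each sub-component uses the hypergeometric polygenic model with
`n = 2k + 1` levels (default `k = 3`, 7 levels per part): level values
`(i - k)/sqrt(k/2)` with Binomial(2k, 1/2) weights (exactly mean 0,
variance 1), parents each transmitting `k` of their `2k` exchangeable
polygenic alleles (hypergeometric sampling). This gives mid-parent
offspring means, a mean segregation variance of half the population
variance, and exact stationarity under random mating — all covered by unit
tests. An individual's level is fixed for life; the age dependence enters
through `sigma(t)` multiplying the level, not through the genotype.

The measured PGS is modelled as a Gaussian read-out of the observed-part
level: `z | A ~ Normal(A, s^2)` with measurement SD `s = 0.4` (about half
the 7-level grid spacing). This keeps the PGS factor a proper density (so
`alpha` is estimable by maximum likelihood), makes `P(z | state)`
well-defined inside peeling, and satisfies the SD decomposition
`(alpha*sigma)^2 + ((1-alpha^2)^(1/2)*sigma)^2 = sigma^2` exactly. The
trade-off: the marginal variance of `z` is `1 + s^2` rather than 1, and the
posterior mean of `A` given `z` is shrunk by `1/(1+s^2)`; percentile-based
scenario tooling accounts for the inflated marginal SD.

### Incidence constraint

For each birth cohort, iterating age by age:
`lambda0(t) = lambda_pop(t) / E[RR | unaffected at t]`, with the genotype
distribution among survivors updated by `exp(-lambda(t|s))` each year. The
conservation property (survivor-average hazard = table rate) then holds to
machine precision at every age; the acceptance suite asserts 1e-8. Because
hazards depend on the birth year only through the rate vector and the
HOXB13 cohort side, identical constraint solutions are shared across birth
years. The bundled `uk_incidence()` table is an approximate England & Wales
male prostate table (five-year bands, pre-PSA-expansion era levels) scaled
so the cumulative risk to age 85 is 16% on the annual grid, matching UK
population estimates for the modelled cohorts; breast/ovarian tables of
realistic magnitude are included as the female information channel.

Risks are cause-specific cumulative risks: **no competing mortality** is
applied anywhere.

### Likelihood and ascertainment

Pedigree likelihoods are computed by exact Elston–Stewart peeling
(iterative elimination of nuclear families; messages normalised in log
space). Loops (marriage/inbreeding) are rejected at validation rather than
cut. Two batched fast paths produce identical numbers to the generic peeler
(asserted to 1e-12 in tests): a vectorised single-nuclear-family engine
used by the fitter, and a factored-kernel engine for cohort-style minimal
pedigrees that never materialises the joint parental state space when only
one non-factorisable vector is attached to the parents.

Ascertainment is adjusted by conditioning. Scheme `proband_phenotype`
divides by the likelihood of the proband's disease phenotype alone
(appropriate under single ascertainment through the proband's diagnosis);
`family_phenotypes` divides by the likelihood of *all* members' phenotypes
with genotypes and PGS marginalised (a deliberate over-conditioning that
stays valid whenever selection depended only on family phenotypes, at an
efficiency cost); `auto` maps symptomatic probands to the former and
screen/unknown-detected probands to the latter, the scheme mix used for
real families; `none` disables adjustment (the sensitivity analysis in
which naive familial aggregation is inflated).

### Fitting

`SegregationModel.fit()` maximises the summed conditioned log-likelihoods
on a transformed scale (logit for frequencies and `alpha`, log for RRs,
`sigma70` and the SD rate) with Nelder–Mead and an optional BFGS polish,
re-constraining the baseline hazards at every evaluation; standard errors
come from the central-difference Hessian on the transformed scale;
convergence tolerance 1e-6 on the log-likelihood. Restarts are available
(`n_restarts`); the default is the supplied starting value only, which is
ample for the low-dimensional fits exercised here — the likelihood is
smooth and the acceptance studies are 1-parameter. `compare()` gives the
AIC table; `SegregationResults.lrt()` performs likelihood-ratio tests after
verifying nesting.

### Prediction and validation

The consultand's posterior state distribution is the peel with the
consultand as terminal pivot, conditioned on being unaffected at the
current age; risks follow as posterior-weighted state-specific cumulative
risks. Model-implied familial relative risks use the same machinery with
survivor re-weighting at each target age. Cohort records are expanded into
minimal pedigrees (father, mother, listed affected brothers, consultand);
when records carry unaffected-relative information (father censor age,
total brother count) it is used, because self-consistent calibration
requires conditioning on everything the records convey — without it,
predictions for FH-negative men are systematically high (observed/expected
about 0.85 in simulation), the mirror image of the under-prediction that
motivates recalibration on real cohorts where unaffected relatives are
unreported.

The C-index is the horizon-truncated Harrell concordance (follow-up
truncated at the horizon, ties counting one half; bootstrap CI over
subjects). Calibration compares mean predicted risks per predicted-risk
decile with Kaplan–Meier observed risks (Greenwood log-log intervals).
Recalibration maps `r -> 1 - (1-r)^c` with a single exponent `c` solved so
the overall expected equals the KM-observed risk; `c` equals the overall
O/E ratio for homogeneous risks, and the root-solve makes the
post-recalibration overall O/E exactly 1 while preserving the ranking.
Missing diagnosis ages of affected relatives can be filled deterministically
from generational age offsets (father = consultand age + 28 by default,
clamped to [40, 89]); unaffected relatives are never invented.

## Synthetic data

`simulate_families` draws founders from the population prior, transmits
states per locus/sub-component, samples event ages by inverse transform on
the constrained annual hazards, and ascertains by rejection under **single
ascertainment**: the candidate proband slot is fixed before phenotypes are
seen and the family is accepted only if that son is affected (plus
arm-specific criteria: young-onset age cut, FH-enrichment). This matches
the proband-phenotype conditioning exactly, which is what makes the
parameter-recovery studies unbiased — an earlier complete-ascertainment
variant (accept if *any* son is affected) biases `sigma70` downward by
about 3 SEs at 2,000 families. Defaults: father+mother, 1 + Poisson(1.5)
sons, no daughters, sons born 1930–1959, observed in 2005; detection-mode
mixture 50% symptomatic / 24% screen / 26% unknown. Each family has its own
random stream derived from `(seed, family_index)`, so subsets are
reproducible independently of `n`.

`simulate_cohort` emulates a UK-Biobank-style prospective cohort: baseline
ages 40–69 weighted toward the early sixties, baseline year 2008, a fixed
28-year paternal generation gap, administrative censoring at 13 years,
BRCA1/2 results available for a configurable fraction (40% in the
acceptance runs), HOXB13 and PGS for everyone. FH summaries are derived
from the hidden simulated family.

What the generator does **not** emulate: self-reported FH under-reporting
and inaccuracy, death of relatives (censoring is purely by age/calendar),
female cancer occurrence in simulated families (female relatives are
generated with unobserved phenotypes; the female likelihood channel is
exercised through hand-built pedigrees in tests), screening-behaviour
dependence on FH, and non-European ancestry. Passing self-consistency tests
therefore demonstrates internal correctness of the machinery — not that the
model is calibrated for any real population.

## Problem sizes and statistical tests

The statistical acceptance studies run on a reduced state space (recessive
locus + 3x3 polygene grids) sized for a single-CPU desk run: one-parameter
recovery fits on 2,000 ascertained families; Wald-interval coverage over
100 replicates of 250 families; null likelihood-ratio calibration over 200
replicates of 120 families; prospective self-consistency on one simulated
cohort of 50,000 men at 5- and 10-year horizons. At n = 50,000 the extreme
predicted-risk deciles contain only a handful of events (their 10-year
risks are a few per mille), so single-run decile O/E ratios carry
Monte-Carlo standard errors of 15–30% there; the per-decile calibration
checks are therefore also asserted in interval form (KM 95% CI covering the
mean predicted risk), which is the statistically meaningful version of the
check at this scale.

## Numerical choices

* State-space sizes are configurable (`SpaceOptions`); scenario tooling
  uses 7x7 polygene grids (3,969 joint states with all four loci), the
  cohort machinery 3x3 or 5x5. Discretisation error is quantified against
  enumeration oracles in the test suite.
* Inactive loci (frequency 0) are dropped from the state space; a positive
  test for an inactive locus is an error rather than a silent zero.
* Peeling messages are renormalised to max 1 with log-scale accumulation;
  impossible data yield `-inf` log-likelihood, and conditioning on an
  impossible event raises.
* Hazard lookups clamp ages to the table range (max age 90 by default);
  rates are zero below the youngest tabulated band.
* The Hessian step is `1e-3 * max(1, |theta|)`; non-positive-definite
  Hessians yield NaN standard errors and a flagged result, not an
  exception.

## Known limitations

No competing mortality; no loop-cutting; no PV-location-specific BRCA2
risks; no grade-specific risks; female breast/ovarian modelling is an
information channel, not a calibrated risk model (and is not constrained to
female incidence by default); the fourth-gene and BRCA/HOXB13 default
inputs are assumptions, not published fits; calibration beyond European
ancestry is out of scope.
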