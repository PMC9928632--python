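# canpros

Pedigree-based prostate cancer risk modelling for men of European ancestry:
complex segregation analysis on cancer families, incidence-constrained
penetrance, absolute-risk prediction for unaffected consultands, and
prospective-cohort validation.

## Who this is for

Statistical geneticists and cancer-epidemiology modellers who need a
transparent, testable implementation of a BOADICEA-style familial risk model
for prostate cancer: fitting genetic models to ascertained families,
predicting a man's future risk from his age, detailed family history (FH),
rare pathogenic variants (PVs) and a polygenic score (PGS), and validating
those predictions against prospective follow-up.

## The model

Prostate cancer incidence for a man with joint genotype state *(G, P)* at
age *t* follows a proportional-hazards form

```
lambda(t | G, P) = lambda0(t) * RR_major(G, t) * exp(sigma(t) * P)
```

* **Major genes** — BRCA2 and BRCA1 (externally assumed age-specific RRs,
  dominant carrier effect), HOXB13 G84E (multiplicative per-allele effect
  with birth-cohort–specific RRs, born before/after 1930), and a
  hypothetical fourth gene, recessive by default (dominant and
  multiplicative variants are available for model comparison). Loci are
  biallelic, in Hardy–Weinberg and linkage equilibrium.
* **Polygenic component (PGC)** — standard normal on the log-hazard scale,
  discretised by the hypergeometric (MENDEL-style) approximation into two
  independently transmitted sub-components; its SD decreases log-linearly
  with age, `sigma(t) = sigma70 * r**(t-70)` (defaults 2.13 and 0.989).
  A fraction `alpha = 0.523` of the SD is explained by the measured PGS;
  the residual part stays latent.
* **Incidence constraint** — `lambda0(t)` is not free: at every age the
  population-average hazard among unaffected men is constrained to equal an
  external incidence table, so genotype-specific risks are consistent with
  population rates by construction.
* **Likelihood** — exact Elston–Stewart peeling over the joint state space,
  with genetic-test factors (configurable sensitivities 0.83 / 0.65 / 1.0
  for BRCA2 / BRCA1 / HOXB13, perfect specificity), a Gaussian PGS
  measurement factor, and breast/ovarian phenotypes of female relatives as
  an information channel for BRCA1/2. Non-random ascertainment is adjusted
  by conditioning: `logL(all data) - logL(data that drove selection)`.
* **Prediction** — the consultand's posterior genotype distribution given
  the family data, converted to cause-specific cumulative risks.
* **Validation** — horizon-truncated Harrell C-index, Kaplan–Meier
  calibration by risk decile, cumulative-hazard-scale recalibration, and
  risk-classification (case-capture) tables.

## Worked example

A 45-year-old consultand (`alex`, born 1968) whose father was diagnosed at
62, with a negative BRCA2 test and a PGS of +0.85 SD, in the documented
tab-delimited pedigree dialect (`canpros.pedigree` docstring):

```
FamID  IndivID  FathID  MothID  Sex  BirthYear  CensorAge  ProstCa ...  BRCA2  PGS   Proband
fam1   father   0       0       M    1938       68         62      ...  0      NA    0
fam1   mother   0       0       F    1940       0          0       ...  0      NA    0
fam1   alex     father  mother  M    1968       45         0       ...  N      0.85  0
```

```sh
canpros predict family.txt --consultand alex --ages 55,65,75,85
```

prints

```
age  55:   1.84%
age  65:  11.51%
age  75:  27.51%
age  85:  40.38%
P(BRCA2 carrier | data) = 0.0007
P(BRCA1 carrier | data) = 0.0016
P(HOXB13 carrier | data) = 0.0067
P(REC carrier | data) = 0.2500
```

The cumulative risk to age 85 (40%) is about 2.6 times the population
figure (16% under the bundled approximate UK incidence table): the affected
father and the above-average PGS both raise the posterior weight of
high-risk genotype/polygene states, while the negative BRCA2 test all but
removes BRCA2 carriership (sensitivity 0.83 leaves a 0.07% residual).
The same computation is available in the library via
`canpros.predict_risk(pedigree, "alex", hazards, ages)`.

Fitting and simulation follow the same pattern (`SegregationModel(...).fit()`
returns a results object with estimates, standard errors, AIC and
`summary()`; `canpros simulate families|cohort` writes synthetic data under
the exact generative model, including ascertainment by rejection).

## Limitations

Risks are cause-specific (no competing mortality). The bundled incidence
table is an approximate England & Wales table; users should supply their
own population rates for other settings. The female breast/ovarian
penetrances are coarse external inputs, used only as an information channel
for BRCA status of female relatives. Default BRCA1/2 and HOXB13
relative-risk curves and the fourth-gene parameters are literature-guided
assumptions documented in `docs/methods.md`; replace them with your own
estimates via the parameter YAML. Pedigrees with marriage or inbreeding
loops are rejected rather than approximated. European-ancestry incidence
and effect sizes only.
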