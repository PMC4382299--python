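# Methods

`carriermod` implements the statistical machinery used to test whether
common SNPs modify breast and ovarian cancer risk in women carrying
pathogenic BRCA1 or BRCA2 mutations, together with a synthetic cohort
generator that reproduces the statistical structure of such data so the
whole chain can be exercised without access to restricted consortium
genotypes.

## The retrospective likelihood

Carriers studied for risk modification are recruited overwhelmingly
through cancer genetics clinics, so sampling depends on disease status: a
prospective likelihood of phenotypes given genotypes is biased under this
design. The analysis core instead models the probability of the observed
*genotypes* conditional on the observed phenotypes,

    L(beta) = prod_i  P(pheno_i | g_i; beta) p(g_i)
                      / sum_{g'} P(pheno_i | g'; beta) p(g'),

which is valid under any sampling scheme that depends on phenotype alone.
`P(pheno | g)` is a survival likelihood on the age scale: an unaffected
carrier observed from entry age `a0` (18 years by default) to exit age
`a1` contributes `S_g(a1)/S_g(a0)`; an affected carrier additionally
contributes the genotype-specific hazard at her diagnosis age. Genotype
g ∈ {0,1,2} counts minor alleles; `p(g)` is a Hardy–Weinberg prior.

### Phenotype construction

Breast analysis: follow-up ends at the first of breast diagnosis, ovarian
diagnosis, bilateral prophylactic mastectomy, or last observation;
carriers whose follow-up ends at ovarian diagnosis count as unaffected.
Ovarian analysis: follow-up ends at the first of ovarian diagnosis,
risk-reducing salpingo-oophorectomy, or last observation; breast cancer is
*not* a censoring event, so ovarian cancer diagnosed after breast cancer
still counts as an ovarian case. ER-subtype analyses treat breast cases of
the other (or unknown) subtype as unaffected, censored at diagnosis — the
convention under which subtype-specific hazard ratios are reported.

### The constrained baseline

The genotype-specific hazards `lam0(t) exp(beta g)` are anchored to a
supplied age-specific carrier incidence `lam(t)` (piecewise constant on an
age grid): interval by interval,

    lam0(k) = lam(k) * [sum_g p(g) S_g(k)] / [sum_g p(g) S_g(k) e^{beta g}],

with `S_g` the genotype-specific survivor function accumulated over the
preceding intervals. By construction the population-average incidence over
the genotype distribution among survivors reproduces `lam(t)` at every
grid point (round-trip checked to 1e-10 relative in the tests). The
baseline is re-solved at every trial `beta` during estimation, so the
anchor holds along the whole profile. Bundled incidence tables are
*illustrative* curves of realistic magnitude (cumulative risk to age 70
roughly 52%/29% for BRCA1 breast/ovarian, 42%/8% for BRCA2); users with
real data must supply their own tables.

### Score test and kinship adjustment

At `beta = 0` the score of the retrospective likelihood reduces to

    U = sum_i (g_i - 2 q)(d_i - H_i),

with `d_i` the affected indicator and `H_i` the cumulative carrier hazard
over the at-risk window. Relatives from one family share alleles, so
per-individual score contributions are correlated; the variance is
computed family-robustly as `V = sum_f (sum_{i in f} u_i)^2` and `U^2/V`
referred to chi-square with 1 df. With singleton families this reduces
exactly to the unadjusted sum of squares. When the allele frequency is
the plug-in sample estimate, the residuals `d - H` are recentred, which
is the influence-function correction for estimating `q` from the same
data (omitting it makes the test conservative under ascertainment).
Monomorphic markers are reported as untestable, never as p = 1. Full
kinship-matrix quadratic forms are not needed for the shallow families
modelled here: family clustering is the exact analogue.

### Hazard-ratio estimation

`estimate_hr` maximises the profile retrospective likelihood over
`beta ∈ [-5, 5]` (bounded scalar minimisation, |Δbeta| < 1e-6), with
per-allele or two-parameter genotype coding. Wald CIs use the
family-clustered sandwich `A^{-1} B A^{-1}` with `A` the numerical
observed information and `B` the sum of squared within-family score sums
(central differences, h = 1e-5 for gradients, 1e-4 for the Hessian).

Allele frequency: the function default is the plug-in estimate from the
observed genotypes (simple and adequate under weak ascertainment), but in
strongly affected-enriched samples the crude frequency is itself enriched
for the risk allele and attenuates `beta` (measured ≈ −0.02 on the log
scale at HR 1.1 with 1:10 retention). `profile_freq=True` maximises
jointly over `(beta, q)` and is the variant used in the bundled studies;
its sandwich treats both parameters as estimated.

### Competing risks

The joint model carries cause-specific hazards `lam_d(t) exp(beta_d g)`
for breast and ovarian cancer, each with its own constrained baseline, on
the first-event phenotype (exit at the first of either diagnosis, either
surgery, or last observation; the cause labels the event). Free
coefficients are estimated simultaneously (Nelder–Mead); either can be
fixed, and fixing `beta_ovarian = 0` on data without ovarian events
reproduces the single-disease breast estimate to machine precision
(asserted at 1e-8). Cross-disease depletion is handled by the first-event
likelihood itself; the per-disease baseline constraint uses each
disease's own survivor weighting.

### Stratified analyses, heterogeneity, subtype contrasts

`stratified_test` fits each stratum separately (own allele frequency and
baseline) and a pooled model with shared `beta`; `heterogeneity_test` is
Cochran's Q over stratum log-HRs; `effect_difference_test` is the Wald
contrast `(betaA - betaB)/sqrt(varA + varB)` for disjoint case groups
(e.g. ER-positive vs ER-negative disease).

## Imputed markers

Imputed markers carry posterior genotype probability triples. The score
contribution of an individual is the posterior-weighted average of her
hard-genotype contributions — because the null score is linear in `g`
this equals scoring the expected dose, and with degenerate posteriors the
hard-call test is reproduced bitwise. Markers are screened on the info
statistic `var(dose)/(2f(1-f))` and on MAF with *strict* inequalities.
The default MAF floor of 0.3 reproduces the source protocol as printed;
a floor of 0.3 excludes most of the genome and is very likely a
typographical artifact of 0.003 or 0.03 — the threshold is configurable
and the code deliberately does not second-guess the printed value.

## Haplotypes

Haplotype frequencies over an explicit SNP window are estimated by EM
under random mating from unphased genotypes (uniform initialisation,
relative log-likelihood tolerance 1e-8, cap 1,000 iterations; random
restarts behind `n_starts` for multimodality checks; missing genotypes
summed over). The four most frequent haplotypes are kept as classes and
the rest pooled into one "rare" class (ties at the cutoff break
lexicographically; total probability conserved exactly). Carriers are
assigned their argmax-posterior diplotype (lexicographic tie-break), and
the per-class dose vectors (summing to 2) enter a standard Cox model of
age at breast diagnosis with the most frequent haplotype as reference.
Assigned doses are the default, matching common practice;
posterior-expected doses are a one-line sensitivity variant.

## Cox engine, interactions, FDR, expression survival

Cox fits delegate to lifelines (Efron ties, left truncation via entry
ages, cluster-robust variance over families). Two numerical notes: a
common entry age before every exit leaves risk sets unchanged, so the
much faster truncation-free path is used in that case; and lifelines'
relative-log-likelihood stopping rule limits point-estimate accuracy to
about 1e-4, so coefficients are polished by BFGS on an exactly matching
Efron partial likelihood (analytic gradient) to agree with brute-force
maximisation to better than 1e-6.

The SNP×SNP scan fits main effects plus a product term per pair. The
default coding is per-allele dose × dose, giving a single 1-df
interaction p per pair; genotype-category contrasts (het/homozygote cell
indicators) are available per pair. Pairs with fewer double carriers than
a configurable minimum (default 10) are skipped with a log entry, and a
scan-level BH-FDR column is appended.

FDR control is Benjamini–Hochberg step-up with an explicitly declared
family size `m >= len(p)` (so a subset of a declared family of, say, 41
SNPs is adjusted against the full family); Benjamini–Yekutieli is
available. Note the step-up transform is not idempotent — re-adjusting
adjusted values can only move them toward 1.

Expression-survival analysis standardises each expression profile (probe
scale invariance), fits the continuous Cox model with a product term, and
emits Kaplan–Meier step functions for the nine tertile-combination groups
(tertile cuts at the empirical 1/3 and 2/3 quantiles, boundary ties to
the lower category; empty combinations are reported, not dropped).

## The synthetic cohort generator

The generator reproduces the features the analysis relies on:

* **Genotypes.** Founder haplotype pairs i.i.d. from a supplied frequency
  vector (HWE; LD between SNPs induced by haplotype structure); families
  are singletons, sib-pairs (latent parents, haplotype-level Mendelian
  transmission), or mother–daughter pairs, giving within-family genotype
  correlation 1/2. Deeper pedigrees would add no additional structure
  for family-clustered inference.
* **Events.** Latent breast and ovarian onset ages are drawn
  independently per cause from `lam0_d(t) exp(beta_d g + b_f)` by exact
  inversion of the piecewise-constant cumulative hazard (no
  discretisation error), with risk accruing from age 18. The baseline is
  constrained in-sample so the simulated cohort's average incidence
  matches the supplied carrier incidence — the generator and the
  analysis therefore agree about what the incidence table means.
* **Familial aggregation.** `b_f` is a family-level normal frailty on the
  log-hazard scale shared by all members and both cancers (default off).
  It models residual familial aggregation — shared modifier loci and
  environment — which the analysis deliberately does not model; this is
  precisely what makes the kinship adjustment necessary on real data.
  Segregation-analysis estimates of the polygenic SD for breast cancer
  (≈1.3–1.7 at birth) imply a shared full-sib component of ≈0.9–1.2
  before shared environment; the calibration study uses 1.2.
* **Censoring.** Uniform last-observation ages (default 20–80 years),
  Bernoulli prophylactic mastectomy (5%, ages 30–60) and oophorectomy
  (10%, ages 35–60), independent of genotype. Events occurring after the
  relevant truncation are blanked, so records contain exactly what a
  registry would have seen.
* **Ascertainment.** Families are retained independently with a
  probability depending on affection status: either any-affected vs none
  (`{"affected": p1, "unaffected": p0}`) or the number of affected
  members (`{"0": .., "1": .., "2": ..}`, "2" meaning two or more). The
  count-based form emulates preferential referral of multiplex families
  and induces *positive* within-family phenotype correlation in the
  retained sample, whereas any-affected retention alone induces negative
  correlation (if one sib is affected the family is in regardless of the
  other). Retention is a stylized stand-in for real clinic recruitment;
  the retrospective likelihood is valid under any phenotype-dependent
  rule.
* **Annotations.** Country-style strata, ER status for breast cases
  (default 70% ER-negative among assigned, 10% unknown) and BRCA1
  mutation class (70% class 1) are assigned at random, independent of
  genotype — they exercise the stratified machinery but carry no signal.
* **Expression cohorts.** Two correlated standard-normal expression
  values per tumour (default correlation 0.3), exponential survival with
  main effects and a product term in the linear predictor, and
  independent exponential censoring tuned to a target censoring fraction
  (1.0 censors everyone at baseline, producing the no-events error path).
* **Dosages.** With probability equal to the target info an individual's
  posterior is a point mass on the truth, otherwise the HWE prior at the
  sample frequency; the realised info statistic then concentrates on the
  target and expected doses are unbiased.

All randomness flows through named streams keyed on the seed (genotypes,
events, censoring, frailty, ascertainment, annotations, dosage,
expression), so one component can be varied with the others held fixed
and fixed seeds give byte-identical output.

What the generator does **not** emulate: genotyping error, deep
pedigrees, population stratification (allele frequencies never differ by
stratum), stratum-specific incidence, calendar-time effects, or
informative (genotype-dependent) censoring. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling and
hazard structure, not robustness to those additional features of real
consortium data.

## Pre-registered studies (carriermod.studies)

Problem sizes were chosen to characterise each property sharply at
desk scale:

1. **Score-test calibration** — 1,000 replicates of 500 ascertained
   sib-pair families (1,000 carriers), frailty SD 1.2, multiplex clinic
   retention (all families with ≥2 affected; 20% of others), follow-up
   ages 35–72, null SNP at MAF 0.25. Reported: rejection rates at
   α = 0.05 with family-clustered and naive variances. Expected
   behaviour: adjusted within the 1,000-replicate binomial band
   [0.037, 0.064]; naive above it (measured 0.053 / 0.073 over 1,500
   independent replicates). The naive demonstration sits ~1 MC standard
   error above the band edge, an intrinsic sensitivity of a
   1,000-replicate design.
2. **Ascertainment correction** — 200 replicates of ~16,000 singleton
   carriers at per-allele breast HR 1.10, retention 1.0/0.1; mean log-HR
   bias of the profiled retrospective MLE vs naive cohort Cox on the same
   data, and Wald CI coverage. Singletons isolate the sampling-bias
   question: with multi-member families, family-level retention
   conditions on the joint family phenotype, which the per-individual
   composite likelihood does not, leaving a separate small attenuation
   (~−0.013 measured at sib-pair mixtures).
3. **Oracles** — analytic score vs central finite differences of the
   log-likelihood (50 cohorts, < 1e-6 relative); Cox vs brute-force
   partial-likelihood maximisation on ≤8-subject tables (< 1e-6); EM vs
   direct simplex ML with independent diplotype enumeration on ≤3-SNP,
   ≤30-individual instances (< 1e-4).
4. **Competing risks** — exact single-disease reduction; joint recovery
   of (log 1.10, 0) at ~16,000 carriers with both surgeries disabled so
   that retention is a function of the analysed first-event phenotype
   (with surgery, a diagnosis can postdate the competing-risks censoring
   event and retention then carries information the analysed phenotype
   does not — a deliberate scope boundary).
5. **Expression interactions** — 5,000 tumours per regime; protective
   (main HRs 1.78/2.07 per SD, interaction 0.57) and aggravating
   (1.78/1.0, interaction 2.16).

`scripts/acceptance.py --seed S --out results/acceptance.json` reruns all
five studies from scratch and writes the measured numbers.

## Known limitations

* The per-individual retrospective likelihood is a composite likelihood
  under family-level sampling; point estimates carry a small attenuation
  when retention depends on relatives' phenotypes (see study 2 above).
* Wald intervals only; profile-likelihood intervals are future work.
* No polygenic/frailty term in the *analysis* likelihood (the robust
  variance absorbs its effect on inference but not on estimation).
* Haplotype association uses standard Cox on assigned diplotypes, not a
  retrospective-likelihood haplotype test.
* The EM enumerates diplotypes compatible with each genotype, which is
  exponential in per-individual heterozygosity; windows are expected to
  be small (a gene locus, ~3–16 SNPs) and highly missing windows are
  rejected.
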