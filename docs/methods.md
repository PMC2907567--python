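# Methods

This note records the statistical models implemented in `famscore`, the
assumptions behind them, the defaults of the synthetic-data generator, and
the numerical and design choices that were genuinely open.

## Score model

The genetic score is an unweighted allele count: marker k contributes
points xₖ ∈ {0, 1, 2} — the number of risk alleles under additive coding,
or 2·1{homozygous risk} under recessive coding — and S = Σ xₖ. The built-in
four-SNP autism panel codes ATP2B2 (rs35678) recessively and the other
three markers additively, so S ranges over 0–8; in practice almost all
individuals fall in 2–8 because three of the risk alleles are common
(frequencies 0.75–0.90). Odd scores are possible (the recessive marker
contributes {0, 2}, but additive markers contribute 1s), and no parity
assumption is made anywhere.

An individual missing a genotype at any scored marker has an undefined
score and is excluded from score-level analyses. No single-marker
imputation is attempted: with a four-marker panel and >97% per-marker call
rates the loss is small, and imputation would entangle the score with the
transmission models being tested.

Risk groups default to low (S ≤ 4), intermediate (5–6), high (S ≥ 7); the
cut points are constructor arguments of `ScoreModel` for other panels.

## Case/pseudocontrol analysis

For each affected, non-index child whose trio is fully genotyped at the
scored markers, the pseudocontrol genotype at each marker is the multiset
of the two parental alleles minus the child's alleles — well-defined
without phasing, and unique even when transmission is phase-ambiguous.
Exactly one pseudocontrol is formed per case (the two untransmitted
alleles); the three-pseudocontrol variant that enumerates all untransmitted
genotype combinations is out of scope. Markers are treated independently
(the panel's loci lie on different chromosomes), so no haplotype
construction is needed. Families missing a required parental genotype drop
out of score-level sets but still contribute single-marker sets at markers
where the trio is complete.

The 1:1 matched conditional likelihood is

L(β) = Π᷈ᵢ exp(βᵀx_case,i) / (exp(βᵀx_case,i) + exp(βᵀx_pseudo,i))
     = Πᵢ σ(βᵀdᵢ),   dᵢ = x_case,i − x_pseudo,i,

an intercept-free logistic model on within-pair differences. It is
maximised by Newton–Raphson from β = 0 to gradient norm < 1e-8 (max 50
iterations). Complete separation (all informative dᵢ of one sign, or a
diverging estimate) and all-zero differences raise typed errors rather than
returning numbers. The variance is the sandwich A⁻¹BA⁻¹ with A the observed
information and B the outer product of *family-summed* scores, so several
affected siblings per family inflate the variance appropriately. No
small-sample cluster correction is applied (matching the GEE convention
below); Wald CIs and p-values are used throughout, since the source
analyses report ORs with 95% CIs without stating an interval method.

This estimator targets the genotype relative risk; under a rare disease it
coincides with the odds ratio, and the package's tests verify the two
designs' estimates agree in the low-prevalence regime.

## Sibling case-control analysis

With genotyped unaffected siblings, affection is regressed on the score (or
single-marker points, risk-group indicators, and covariates such as sex) by
GEE with a logit link and the independence working correlation — point
estimates identical to ordinary logistic ML, standard errors from the
family-clustered robust sandwich (statsmodels `GEE`). The IQ check uses the
identity link (ordinary least squares point estimates) with the same
clustering, regressing IQ on score adjusted for sex and affection status; in
the generator IQ is independent of the score by construction, so this
analysis is a null-calibration probe.

Degenerate inputs (single-class outcome, constant predictor, non-finite
robust SEs) raise typed errors; optional pipeline stages catch them and
record a warning instead of failing the run.

## Category ladder and risk groups

The per-score odds-ratio table is reported in log-linear mode by default:
OR(s) = exp(β̂·(s − s₀)) with s₀ the minimum observed score (reference), and
CI exp((β̂ ± 1.96·se)·(s − s₀)). This reproduces the geometric ladder that a
linear-in-score model implies; a categorical (indicator) fit is available
through the same fitting functions for panels where log-linearity is in
doubt. Risk-group ORs are fitted with indicator predictors (conditional
logistic on indicator differences, or GEE with two group indicators),
low as reference.

## Discrimination

The threshold convention is S ≥ γ (ties positive), so the lowest observed
threshold always yields sensitivity 1 and specificity 0. With true
controls both quantities are direct proportions with Wald binomial CIs.
Without controls, specificity is inverted from the threshold OR:

spec_γ = OR_γ·(1 − sens_γ) / (sens_γ + OR_γ·(1 − sens_γ)).

Applied with the crude 2×2 odds ratio this is an exact algebraic identity
with the direct specificity (property-tested to 1e-12); in the pipeline
OR_γ comes from conditional logistic regression on the dichotomised score,
which respects the matching. Where that fit is degenerate (no informative
pairs, or separation at extreme thresholds) the crude OR is substituted and
the row's `source` column says so. At sens ∈ {0, 1} the formula is
undefined and the limiting specificity (1 or 0) is returned with a boundary
flag; boundary rows are reported but excluded from cross-design
consistency comparisons.

AUC is the Mann–Whitney C-statistic with ties counted one-half, computed
from midranks; it equals the trapezoidal area under the ROC staircase over
all integer thresholds (exactly, for integer scores). Confidence intervals
resample whole families (cases and controls of a family travel together),
1000 replicates by default, seeded.

A caution on estimands: the untransmitted-allele pseudocontrol distribution
approximates the *population* genotype distribution (the allele-frequency-
based-control property), whereas unaffected siblings of multiplex families
are genotypically risk-enriched. Formula-based and sibling-control
specificities therefore agree within sampling error at moderate effect
sizes but are not the same parameter; `cross_design_spec_ci` and
`bootstrap_formula_spec` quantify the comparison, and the latter offers a
Bonferroni-adjusted joint band for simultaneous "at every threshold"
statements.

## Marker-attributable λs

Each locus contributes λs = 1 + (V_A/2 + V_D/4)/K² where, for genotype
relative risks (f₀, f₁, f₂) at HWE frequencies (q², 2pq, p²): K is the mean
risk, V_A = 2pq·α² with α = p(f₂−f₁) + q(f₁−f₀), and
V_D = (pq)²·(f₀ − 2f₁ + f₂)². Genotype risks derive from the fitted
per-allele OR (treated as a relative risk): additive → (1, r, r²),
recessive → (1, 1, r). Loci combine multiplicatively (independence). The
per-locus formula is verified in tests against brute-force enumeration of
sib-pair joint genotype probabilities. Reports flag the OR→RR substitution
and the multiplicative assumption explicitly; monomorphic loci contribute
λs = 1 with a warning.

## Quality control

* **HWE**: exact conditional test on founder genotype counts — the
  probabilities of all heterozygote counts compatible with the observed
  allele counts are summed over configurations no more probable than the
  observed one (no mid-p). Computed in log-space with a tie tolerance of
  1e-12 relative. The exact test is conservative; simulation under HWE
  shows rejection ≤ 5%.
* **Mendelian checks**: a child genotype is inconsistent when it cannot be
  formed by one allele from each parent; trios with any missing genotype at
  a marker are skipped (no imputation). Families with ≥1 inconsistency are
  excluded wholesale; the re-typing remedy applied in wet-lab workflows has
  no software counterpart here.
* **Missingness**: per-marker missing fractions are computed over
  individuals with at least one non-missing genotype, so deliberately
  ungenotyped unaffected siblings do not count against a marker. Markers at
  or above the 5% threshold are flagged, never dropped (the field remedy is
  re-genotyping).
* **Index cases**: one affected child per family is flagged as index — the
  oldest, interpreted through the dataset's ordering semantics (maximum
  age, or minimum birth order, depending on which sample-info column was
  supplied). Ties and missing ordering fall back to the smallest individual
  ID with a logged warning. Index cases are excluded from every
  association and discrimination analysis, which also serves as an
  ascertainment correction (see below).

## Synthetic-data generator

The generator emulates the structure the analyses assume, not any
particular cohort's raw data:

* Parental genotypes under HWE at configured risk-allele frequencies
  (defaults: the AGRE panel estimates 0.89/0.45/0.90/0.75); children
  receive one uniformly chosen allele per parent per marker, independently
  across markers (no LD, no mutation).
* Affection follows logit P(affected) = α + Σ βₖxₖ with a single per-point
  slope β = ln(1.33) by default (per-marker slopes available for
  single-marker experiments). The intercept α is calibrated by bisection on
  the exact score distribution so the *unascertained* sibling prevalence
  hits a target, 10% by default — the approximate recurrence risk in
  siblings of an affected child; ascertainment then shifts observed rates,
  as in real multiplex collections. The disease model is deliberately
  logistic in the score itself so that per-point parameter recovery is
  well defined.
* Sibship sizes default to 2/3/4 with probabilities 0.55/0.33/0.12
  (chosen once as a realistic multiplex-collection mix averaging ~2.6
  children); ascertainment is rejection sampling — `agre_like` keeps
  families with ≥2 affected children and masks unaffected siblings'
  genotypes, `seattle_like` keeps families with ≥1 affected and ≥1
  unaffected child, all genotyped (`mask_unaffected` overrides the masking
  for same-families design comparisons). An acceptance probability below
  1e-4 raises a diagnostic error instead of looping.
* Affected children are male with odds 3.5:1; unaffected children 1:1.
  IQ is drawn independently of genotype — affected ~ N(76.3, 26.1),
  unaffected ~ N(111, 16.3), matching the descriptive moments of a
  genotyped-control family collection. Ages decrease by 2 years per birth
  order from a family-specific eldest age.
* One RNG stream per run; the seed and calibrated intercept are recorded in
  dataset provenance, and equal seeds give bit-identical datasets.

What the generator does *not* emulate: linkage disequilibrium between
panel markers, population stratification and admixture, genotyping error
processes (errors are injected only deliberately via `inject_errors`),
de-novo events, diagnostic misclassification, and any IQ–genotype
dependence. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model — not robustness
to those real-data complications.

Ascertainment and the index case: selecting families through affected
children enriches parental risk alleles; excluding one affected child per
family largely removes the induced bias in sibling case-control estimates
(verified by simulation: with index exclusion the large-sample per-point
OR is within ~0.015 of the generating 1.33; without it, attenuation to
~1.17). In null-calibration experiments the package uses multiplex
families with genotyped controls so that both designs retain enough cases
after index exclusion for Wald asymptotics to apply; sparse-case regimes
(a handful of affected among hundreds) show the usual Wald over-rejection
of sparse logistic models and are not informative about calibration.

## Problem sizes used in the checks

The test suite and the reproduction script run entirely on simulated data
at sizes chosen to give stable Monte-Carlo estimates: 200,000 individuals
for the population AUC; 20 replicates of 2,000 multiplex families for
pseudocontrol parameter recovery (at 2% baseline prevalence, the
rare-disease regime where the conditional-logistic relative risk equals
the generating OR); 200 replicates of 240 families for sibling
case-control recovery and CI coverage; 500 replicates of 150 families for
null calibration; 40 replicates of 240 families for cross-design
specificity consistency.

## Known limitations

* Wald inference throughout; no exact conditional inference or Firth
  correction, so extreme-threshold ORs from near-separated fits are
  reported with very wide CIs or fall back to crude estimates.
* λs combines loci multiplicatively and converts ORs to RRs directly;
  both are approximations at a 10% recurrence risk.
* The score is unweighted; weighted or interaction-aware scores are out of
  scope.
* Nuclear families only — no multi-generation pedigrees, half-sibs or
  inbreeding loops; VCF/BCF and binary PLINK inputs are not supported.
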