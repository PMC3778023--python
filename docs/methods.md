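# Methods

This note records the statistical model the package implements, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Risk model

Each genetic risk factor is a published per-allele odds ratio `OR` with a
95% CI and a control-population allele frequency; the environmental factor
(male ever-smoking) is a published exposure OR with CI and an exposure
prevalence.  A profile's summary log OR is the dosage-weighted sum of
per-factor log ORs, and its variance the corresponding sum of `k²σ²` terms —
a multiplicative model assuming risk-factor independence.  Consequences of
that form:

* **Genotypes are allelic-dosage multiplicative**: a homozygote carries the
  allelic OR squared and variance `4σ²`.  Published sources supply allelic
  ORs only, so no genotype-level model is attempted.
* **Precision** `σ` is recovered from the published CI,
  `σ = (ln hi − ln lo) / 2z`, because the CI is the directly published
  precision.  When only discovery sample sizes are available the fallback is
  the Woolf SE on expected allele counts (`se_from_counts`), with the case
  frequency implied by the OR and control frequency.  Frequencies of exactly
  0 or 1 make the Woolf SE incomputable and raise rather than guess.
* **HLA-DRB1 is one multi-allelic locus.**  Each of the two carried alleles
  contributes one allelic OR term; modelled four-digit alleles take their
  own OR, alleles known only at two digits (or whose subtype is unmodelled)
  take the two-digit group OR, and an allele never contributes both its
  four-digit OR and its two-digit parent.  Alleles with no published OR
  contribute nothing (they are baseline, not grounds for exclusion).
* **No interactions and no linkage disequilibrium**: gene–gene and
  gene–environment interaction terms (shared epitope × smoking,
  PTPN22 × HLA) are deliberately absent — published interaction estimates
  are too heterogeneous to pool — and SNPs are treated as independent.

## Population simulation and categorisation (stage 1)

Profiles are drawn from general-population frequencies: SNP dosages
`Binomial(2, f)` under HWE; the HLA allele pair as two independent
categorical draws over modelled four-digit alleles, two-digit residual mass
(group frequency minus its modelled subtypes), and an "other" remainder;
exposures as Bernoulli draws.  Models with ≤ 12 factors and ≤ 10⁶ genotype
states are enumerated exactly with HWE weights (the packaged HLA model, with
23 allele classes, enumerates to 276 genotype states); larger models are
Monte-Carlo sampled with a default of m = 100,000 profiles, enough to make
category-boundary placement stable across seeds for the packaged models
while keeping stage 1 under a couple of seconds.

Raw log ORs (relative to a no-risk-factor profile) are shifted by
`ln(mean OR)` so the **arithmetic**-mean-OR profile sits at exactly 1.0.
The arithmetic mean is used because it makes population-mean risk consistent
with downstream prevalence scaling; `calibrate` accepts weights, so a
geometric-mean sensitivity variant is one line if wanted.

Category boundaries are frozen from the calibrated distribution after
collapsing duplicate profiles (so "the first elevated profile" is
well-defined):

* the **baseline** profile is the one nearest OR 1.0 on the log scale (ties
  broken toward smaller variance — the paper-level description "the profile
  of baseline risk" does not define nearness, so this is an implementation
  choice);
* CIs overlapping the baseline CI are **average**, with a shared endpoint
  counting as overlap ("resides fully below/above" implies strict
  separation for the non-average classes);
* fully below → **reduced**; fully above → **elevated**; fully above the
  first elevated profile's CI → **high**.  When no profile lies fully above
  baseline, the elevated/high classes are empty.

Narrowing every CI (better-powered discovery studies) can only move
profiles out of "average"; this monotonicity is asserted as a property test.

## Individual scoring (stage 2)

Individuals are scored with the same factor model and calibration shift, so
a person whose genotype equals a simulated profile reproduces that profile's
OR and category exactly (tested).  Eligibility rules per model: smoking
models are male-only and require known smoking status; SNP models require
every modelled dosage; HLA models require at least one typed allele — a
person typed on one allele only is scored on the known allele rather than
excluded (the source description is silent on this; excluding would discard
genuine information).  Allele codes are normalised from `0401`,
`DRB1*04:01`, `*04` styles to `*04:01` / `*04`.

Lifetime risk = summary OR × 2.4% (women) or 1.1% (men), capped at 100%.
The OR→relative-risk approximation is applied as published, without a
rare-disease correction; the cap is a safety valve (the largest value the
packaged model produces in practice is well below it).

## Evaluation

AUC is the Mann–Whitney probability with ties counted half; variance and
the paired test for correlated AUCs use DeLong's structural components
(cross-checked against R pROC to 6 significant figures in the tests, and
against a jackknife oracle at small n).  2×2 exposure ORs use the Woolf
log-normal CI with Haldane–Anscombe +0.5 only when a cell is empty
(flagged); an empty margin is undefined and raises.  Published cohort
smoking CIs were evidently computed by a different (likely regression-based)
method, so point ORs are the comparison surface and CIs are merely reported.
P-values are two-sided with no multiplicity adjustment.

## Age of onset

Kaplan–Meier curves and the k-sample log-rank test are implemented natively
(with censoring support and the aggregate-increment convention for ties),
and cross-checked against lifelines.  The pipeline analysis is case-only
with fully observed onset ages, where the product-limit estimator reduces to
the empirical CDF; the median is the smallest age at which cumulative
incidence reaches one half.  Multivariate Cox modelling is out of scope;
`cox_export` emits a tidy (onset age, OR score, sex, smoking,
sex × smoking) table for standard survival tooling.

## Synthetic cohorts

The generator emulates the structure of the access-controlled case-control
cohorts this kind of model targets:

* disease status is logistic in the calibrated log OR, with the intercept
  solved numerically so simulated population prevalence matches the target
  (default 0.8%, the UK adult RA prevalence estimate the calibration
  literature uses).  In this rare-disease regime the generative ORs match
  the published ORs to good approximation, and a joint logistic refit on a
  20,000-person cohort covers the generating log ORs at nominal rates
  (the parameter-recovery test requires ≥ 90% coverage);
* cohort composition is by design: cases 76% female, controls 50%
  (mirroring the larger source cohort's clinical table), with genotype and
  smoking rejection-sampled conditional on status so case/control allele
  frequencies and the male smoking exposure OR (3.02) emerge from the
  disease model rather than being imposed;
* smoking prevalence is sex-specific (57.1% / 57.7%, the source control
  rates); smoking is generated independently of genotype, matching the
  independence assumption, and its disease effect applies to males only;
* HLA typing resolution is masked per person (68% four-digit / 10%
  two-digit / 22% mixed, the reported control availability), with ground
  truth retained in sidecar columns for tests;
* onset ages follow a Weibull proportional-hazards model, baseline shape 4
  and scale 55 years (median onset ≈ 50, matching the reported onset
  distribution), hazard multiplier `1.026^(OR score) × 0.848^(ever-smoker)`
  — the published per-OR-unit HLA and ever-smoking hazard ratios;
* missingness is MCAR at per-field rates (smoking 20%, SNP 1% by default).

**What passing tests show — and do not.**  The generator reproduces exactly
the assumptions the prediction model makes (independence, HWE, logistic
disease risk, no LD, no population stratification, no assortative
missingness, no genetic difference between serostatus labels).  Tests
therefore demonstrate internal consistency and correct implementation, and
direction-of-effect results (HLA model AUC exceeding the SNP model's,
high-risk cases having earlier onset, ever-smokers later onset) at desk
scale — not real-data performance.  Published cohort AUCs, category
percentages and log-rank statistics depend on the access-controlled data
and are not reproducible here; synthetic AUCs run slightly above the
published ones precisely because the generative model matches the scoring
model.

## Problem sizes and numerics

Default analysis sizes: stage-1 Monte Carlo m = 100,000; synthetic
discrimination cohorts 2,000 + 2,000; onset analyses pool three 2,000-case
cohorts; parameter recovery 10,000 + 10,000.  The intercept solver brackets
on [−40, 20] with Brent's method (tolerance 1e−10 on α); duplicate-profile
collapsing rounds calibrated log ORs at 12 decimals; z-quantiles are always
computed from the normal distribution, never hard-coded.  Rejection
sampling of cases at 0.8% prevalence draws ~125 candidates per accepted
case and is bounded (raising rather than looping forever under extreme
configurations).

## Known limitations

* The CI-derived SE is itself a choice; discovery-size-based precision
  (Woolf) is available but not the default, and the two differ slightly.
* Wald CIs on rare HLA alleles (frequency < 1%) are approximate at cohort
  sizes in the tens of thousands.
* The lifetime-risk conversion ignores competing mortality and assumes the
  published baseline lifetime risks transfer across populations.
* The categoriser depends on the simulated population through two frozen
  intervals only; pathological models in which no profile CI brackets 1.0
  would yield a baseline CI not containing 1.0 (none of the packaged models
  do).
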