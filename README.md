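# rapredict

Simulation-based risk prediction for rheumatoid arthritis (RA) from published
risk-factor summary statistics, with confidence-interval-based risk
categorisation and age-of-onset analysis.

## The problem

Seropositive RA risk is dominated by *HLA-DRB1* alleles, with smaller
contributions from ~30 non-HLA SNPs and, in men, ever-smoking.  Combining
these published effects into an individual risk estimate raises three
practical problems this package addresses:

1. **Turning published odds ratios into a personal risk.**  Under risk-factor
   independence a profile's summary odds ratio is multiplicative:
   `log OR = Σᵢ kᵢ·ln ORᵢ + Σₑ xₑ·ln ORₑ`, with `kᵢ ∈ {0,1,2}` the
   risk-allele dosage and `xₑ ∈ {0,1}` the exposure indicator, and variance
   `Σᵢ kᵢ²σᵢ² + Σₑ xₑσₑ²` with each `σ` recovered from the published 95% CI
   (or Woolf expected counts when only discovery sample sizes are known).
2. **Categorising that risk against the general population without a
   reference cohort.**  Stage 1 simulates (or, for small models, enumerates
   under Hardy–Weinberg weights) the population distribution of risk
   profiles, rescales so the population-mean OR is 1.0, and freezes four
   categories from the profile CIs: *average* (CI overlaps the baseline
   profile's CI), *reduced* (CI fully below), *elevated* (CI fully above),
   and *high* (CI fully above the CI of the first elevated profile).
   Because the boundaries are CI-based, imprecisely estimated risks are not
   classified as extreme.
3. **Scoring real people.**  Stage 2 applies the same calibration to
   individual genotype/exposure records, handling *HLA-DRB1* typing at mixed
   two-/four-digit resolution (each carried allele is scored once, at the
   highest resolution at which it is known), applying per-model eligibility
   rules, and converting summary ORs into lifetime risks by scaling the
   published baselines (2.4% women, 1.1% men; ORs approximate relative risks
   at low prevalence).

Evaluation utilities cover ROC/AUC with DeLong variance and the paired
DeLong comparison of correlated AUCs, Woolf 2×2 odds ratios, category
cross-tabulations, ordered risk-distribution exports, and case-only
Kaplan–Meier / log-rank age-of-onset analysis.  Because the cohorts this
kind of model is fitted to are access-controlled, a synthetic cohort
generator (`rapredict.synthetic`) emulates their structure from the
published summary statistics alone, including disease status under a
logistic model in the calibrated log OR and Weibull proportional-hazards
onset ages.  See `docs/methods.md` for the full model description.

## Worked example

Score a male ever-smoker typed *04:01 at four digits on one allele and *04
at two digits on the other, under the HLA-plus-smoking model:

```python
from rapredict import (
    bundled_model, bundled_configs, simulate_population, build_categoriser,
    IndividualRecord, score_individual,
)

model = bundled_model()                       # packaged published ORs
config = bundled_configs()["HLA_smoking"]     # 25 HLA alleles + ever-smoking

pop = simulate_population(config, model, m=100_000, seed=17)   # stage 1
cat = build_categoriser(pop)
print(f"baseline CI: ({cat.baseline_low:.2f}, {cat.baseline_high:.2f})")

person = IndividualRecord(
    id="P001", sex="male", status="case",
    hla_allele_1="*04:01", hla_allele_2="*04",
    ever_smoker=1,
)
risk = score_individual(person, config, model, cat)            # stage 2
print(f"summary OR: {risk.or_point:.1f} (95% CI {risk.ci_low:.1f}-{risk.ci_high:.1f})")
print(f"category: {risk.category}")
print(f"lifetime risk: {risk.lifetime_risk_pct:.1f}%")
```

Output:

```
baseline CI: (0.67, 1.48)
summary OR: 15.0 (95% CI 11.5-19.6)
category: high
lifetime risk: 16.5%
```

The summary OR of 15 multiplies the *04:01 allelic OR (4.14), the *04
group OR (3.71) for the second allele and the male ever-smoking OR (3.02),
rescaled so a population-mean profile has OR 1.0; the CI lies fully above
the first elevated profile's CI, so the person is high-risk, and his
lifetime risk is 15.0 × 1.1% = 16.5%.

The same pipeline is available from the shell:

```sh
rapredict synth --model HLA_SNP --n-cases 2000 --n-controls 2000 --seed 17 --out cohort.tsv
rapredict build --model HLA --m 100000 --seed 17 --out categoriser.json
rapredict score --categoriser categoriser.json --cohort cohort.tsv --model HLA --out risks.tsv
rapredict evaluate --risks risks.tsv --out report.json
rapredict yora --risks risks.tsv --out yora.json        # age-of-onset analysis
```

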