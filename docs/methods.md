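# Methods

## The analysis model

All inference is by maximum-likelihood logistic regression on a binary
outcome Y (MGUS status in the motivating application). The base interaction
model is

    logit P(Y = 1) = β₀ + β_age·age + β_sex·male + β_g·GRS + β_s·SEP
                     + β_int·GRS·SEP

with GRS a continuous risk allele count and SEP a 0/1 indicator (high
education or high income, low as reference). Two interaction scales are
reported from the same fit:

- **multiplicative**: OR_int = exp(β_int) per one-allele GRS increment,
  Wald 95% CI exp(β_int ± 1.96·SE);
- **additive**: RERI = exp(c·β_g + β_s + c·β_int) − exp(c·β_g) − exp(β_s) + 1
  for GRS increment c (default 1 allele). RERI = 0 under additivity of
  risks; RERI > 0 means the joint exposure exceeds the sum of the separate
  effects.

The RERI variance uses the delta method: var = gᵀΣg with
g = (e^u − e^{b_g}, e^u − e^{b_s}, e^u), u = b_g + b_s + b_int, where the
coefficients and Σ are pre-scaled by the GRS increment. A percentile
bootstrap (refitting on row resamples) is available as a cross-check; the
delta method is the default because it is deterministic and is the standard
Hosmer–Lemeshow construction. When the SEP main effect is protective
(OR < 1) some authors recommend re-referencing to the lowest-risk category
before computing RERI; this is available behind a flag (with a warning that
the estimate changes meaning) but is off by default so that results computed
from a fit's coefficients match what those coefficients imply directly.

Other design choices, fixed deliberately:

- **Wald CIs throughout**; profile likelihood is not used.
- **No multiple-testing adjustment** anywhere (the per-SNP scan reports raw
  Wald p-values); stated rather than hidden.
- **Complete-case exclusion is per model**, never global: each model drops
  and counts only rows missing that model's variables, so n varies across
  tables exactly as it does in per-analysis reporting practice.
- **Convergence**: Newton iterations to relative log-likelihood change
  < 1e-10, max 100 iterations. Separation is flagged when any non-intercept
  coefficient exceeds 15 on the log-odds scale; flagged fits are returned
  with `converged=False`, never silently.
- **Joint effects** enter all GRS-tertile × SEP-category combinations as
  dummies in a single age/sex-adjusted model against the (lowest tertile,
  lowest SEP) reference; empty cells are dropped with a warning and marked
  inestimable.
- **Extended (mediation-check) models** add, for one risk factor at a time,
  its main effect plus GRS×RF and SEP×RF product terms, and report the
  GRS×SEP OR and RERI from the extended fit for comparison with the base
  model. This is a term-extension check, not a causal mediation
  decomposition.

## Score construction and coding rules

- GRS = sum of risk-allele dosages over the panel; fractional imputed
  dosages are summed as-is (hard-calling available behind a flag). A sample
  missing any panel SNP (after proxy substitution) gets a missing score
  under the default policy, mirroring complete-case scoring.
- Proxy markers substitute **only** for samples missing the primary SNP;
  the panel file must declare the proxy's risk allele — LD phase is never
  inferred automatically, because silent phase guessing is a classic source
  of sign errors.
- Tertiles and sex-specific income quartiles/medians use lower
  order-statistic (type-1) quantiles, so label assignment is rank-stable
  across platforms and never depends on interpolation; ties at a cut point
  go to the lower group. "High income" is strictly above the sex-specific
  median.
- Education bands are ≤10 / 11–13 / 14–17 / ≥18 years with the low/high
  split at 14 years. eGFR exactly 30 mL/min uses the standard (non-renal)
  free-light-chain ratio range — the boundary is inclusive upward, since
  the defining rules name "< 30" and "> 30" and leave 30 unassigned.
- FFQ labels are fixed to the five-level vocabulary (daily, 4–6 times/week,
  1–3 times/week, 1–3 times/month, hardly ever/never); vegetables and fruit
  are "low" from 1–3 times/week down, fish from 1–3 times/month down.
  Unknown labels raise with the accepted list.

## The synthetic cohort generator

The generator is a stated world, not a tuning dial: its defaults encode the
cohort the analysis is designed for, and tests measure against that world.

- n = 4329 participants, age ~ U(45, 75), 50% female, outcome prevalence
  calibrated to 5.5% by solving for the intercept (deterministic root find
  on the mean inverse-logit).
- Effect sizes default to published interaction-model estimates: per-allele
  OR 1.01, high-SEP OR 0.58, GRS×SEP OR 1.17, age OR 1.04/yr, male OR 1.39.
- The default 10-SNP panel's risk-allele frequencies (0.10–0.45, mean
  0.265) were chosen so the score reproduces the published score moments
  (mean ≈ 5.3, sd ≈ 2.0) under HWE independence; an alternate panel config
  (`config_grs2019`) averages 0.45 for a score mean ≈ 9.0. Per-SNP
  frequencies of the real panels are not public, so these are moment
  matches, not estimates.
- Proxy pairs are generated as two-locus haplotypes with
  D = √(r²·p₁q₁p₂q₂) (positive phase), collapsed to genotype dosages; the
  feasibility bound D ≤ min(p₁q₂, q₁p₂) is enforced with an explicit error
  naming the maximum attainable r². Defaults: one pair at r² = 0.86
  (alternate panel: 0.73).
- Education years follow a 15-point categorical matched to the published
  band frequencies (11.3/55.8/22.5/10.4%); household income is log-normal
  (μ = 7.71, σ = 0.25 on the log scale) divided by a categorical household
  equivalisation weight (1.0/1.5/2.1/2.8), approximating the published
  median equivalised income ≈ €1450/month. The weight scheme itself is an
  input, not computed, since equivalence scales vary.
- Raw risk-factor fields are generated so their **coded** prevalences match
  the published cohort (smoking 58%, obesity 27%, diabetes 13.6%, low
  fish/boiled-veg/raw-veg/fruit 63/63/69/31%): BMI is normal with sd 4.6
  and mean solved from the obesity target; glucose criteria contribute ~7%
  and diabetes history tops up the union; FFQ categories are sampled with
  the low-consumption mass fixed at the target.
- Genotype and SEP are generated independently (the standard G×E null
  structure); no marginal gene–environment correlation is asserted.
  Population stratification, imputation uncertainty, chip batch effects and
  longitudinal visit structure are deliberately absent — a green test
  establishes the statistical machinery, not robustness to those
  real-data features.
- Determinism: one seed per cohort; genotype, covariate, outcome and
  missingness streams are spawned from it deterministically, so identical
  configs give byte-identical fixtures. Missingness is opt-in per column.

## Numerical and testing notes

- The logistic fitter is statsmodels' Newton ML; tests cross-check it
  against a closed-form saturated 2×2 solution (log cross-product ratio to
  1e-8) and an independent scipy minimisation of a hand-written likelihood
  (1e-6).
- Stochastic checks are seeded and sized to their purpose: interaction
  recovery at n = 100,000 (100 replicates), delta-CI coverage at study
  scale n = 4,000 (300 replicates), null calibration of the Wald test (500
  replicates), bootstrap-vs-delta agreement at n = 100,000 with 200
  bootstrap replicates (kept below the suite's time budget; the percentile
  endpoints are stable well within the 20%-of-width agreement band being
  checked).
- Degenerate inputs fail loudly: single-class outcomes, all-equal scores
  (tertiles), all-equal incomes within a sex, non-positive household
  weights, zero λ light chains, dosages outside [0, 2], infeasible LD
  targets, unknown FFQ labels.

## Known limitations

- RERI for a continuous GRS depends on the chosen increment and on the
  covariate pattern only through the fitted coefficients (it is a
  coefficient functional, not a standardised population quantity).
- The bootstrap CI resamples rows i.i.d.; no clustering or stratified
  resampling.
- The per-SNP scan reuses the cohort once per SNP; its directional
  consistency summary is descriptive, not a test.
- VCF support reads DS/GT for bi-allelic records only and requires cyvcf2.
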