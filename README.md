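# gxsep — gene-by-socioeconomic-position interaction analysis

`gxsep` is a Python toolkit for studying whether the effect of a polygenic
risk burden on a binary disease outcome differs across social strata. It was
built around the epidemiology of monoclonal gammopathy of undetermined
significance (MGUS) — an asymptomatic premalignant plasma-cell disorder whose
known common risk variants have small effects that may be modified by
socioeconomic position (SEP) — but every component is generic to a
gene–environment (G×E) analysis with an unweighted allele score and a binary
or categorical environmental indicator.

The package covers the full pipeline:

- **Genetic risk scores** (`gxsep.grs`): unweighted risk allele sum scores
  GRS = Σᵢ dᵢ over a fixed SNP panel, where dᵢ ∈ [0, 2] is the (possibly
  imputed) risk-allele dosage at locus *i*. Panels may declare proxy markers
  in linkage disequilibrium (r²) for loci missing on some genotyping chips;
  allele orientation is always explicit — there is no silent strand
  flipping. GRS tertiles with deterministic tie handling.
- **SEP and risk-factor coding** (`gxsep.sep`): years-of-education bands
  (≤10, 11–13, 14–17, ≥18) and a low/high split at 14 years; household
  income equivalised by a household weighting factor, with sex-specific
  quartiles and a sex-specific median split; WHO obesity (BMI ≥ 30),
  glucose/history/medication-based diabetes, smoking, and food-frequency
  (FFQ) dichotomisations; serum free light chain κ/λ ratio flags with
  eGFR-dependent reference ranges.
- **Interaction models** (`gxsep.models`): maximum-likelihood logistic
  regression (via statsmodels) with per-model complete-case exclusion and
  honest convergence/separation flags. On top of the fitted coefficients the
  package computes:
  - the **multiplicative interaction OR** — exp(β_int) of the GRS×SEP
    product term, with Wald 95% CI;
  - the **relative excess risk due to interaction** on the additive scale,

        RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1
             = exp(b_g + b_s + b_int) − exp(b_g) − exp(b_s) + 1,

    which is 0 when risks combine additively. Its 95% CI uses the delta
    method on the (b_g, b_s, b_int) covariance submatrix, with a percentile
    bootstrap as a cross-check;
  - SEP-stratified GRS effects, single-reference **joint effects** of GRS
    tertile × SEP category dummies, risk-factor-**extended** interaction
    models (mediation check), and per-SNP interaction scans with
    directional-consistency summaries.
- **Synthetic cohorts** (`gxsep.simulate`): a seeded generator producing
  genotypes under Hardy–Weinberg equilibrium with controllable proxy-pair
  LD r² (two-locus haplotype simulation), realistic covariate marginals, and
  outcomes from a logistic model with configurable age, sex, GRS, SEP and
  GRS×SEP log-odds. Defaults emulate a population-based cohort of n = 4329
  with ~5.5% outcome prevalence and published effect sizes, so the whole
  pipeline is testable without access to participant data.
- **I/O and reporting** (`gxsep.io`, `gxsep.report`): phenotype CSV, dosage
  TSV and VCF (DS or GT) readers, YAML analysis configs, a one-call
  `run_analysis` driver, and deterministic CSV/Markdown table rendering.

## Worked example

```python
from gxsep import SimulationConfig, simulate_cohort, interaction_model
from gxsep.report import prepare_cohort

cohort = simulate_cohort(SimulationConfig(seed=7))      # n=4329, ~5.5% prevalence
df = prepare_cohort(cohort.phenotypes, cohort.genotypes, cohort.panel)
res = interaction_model(df, sep="education_high")
print(f"n = {res.n} ({res.n_case} cases)")
print(f"OR_interaction = {res.or_interaction:.2f} "
      f"({res.or_ci[0]:.2f}; {res.or_ci[1]:.2f}), p = {res.p_interaction:.2f}")
print(f"RERI = {res.reri:.2f} ({res.reri_ci[0]:.2f}; {res.reri_ci[1]:.2f})")
```

prints

```
n = 4329 (241 cases)
OR_interaction = 1.19 (1.04; 1.37), p = 0.01
RERI = 0.07 (0.02; 0.12)
```

The generator's default interaction OR is 1.17 per risk allele for high vs
low education; this draw refits it as 1.19 (within sampling error at study
scale). The positive RERI says the joint effect of carrying more risk
alleles *and* being in the high-education group exceeds the sum of the two
separate effects — additive-scale interaction, the scale usually argued to
indicate biological synergy.

The same pipeline runs from the shell:

```bash
gxsep simulate --seed 7 --out cohort/
gxsep run --phenotypes cohort/phenotypes.csv --genotypes cohort/genotypes.tsv \
          --panel cohort/panel.tsv --out results/
gxsep report --bundle results/results_bundle.json
```

`src/gxsep/data/` ships two 10-SNP panel templates; all rsIDs and risk
alleles other than the documented proxy pairs are placeholders to be filled
from the relevant GWAS supplementary tables.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, through `gxsep.models.compute_reri`, the additive-interaction
estimates that are deterministic functions of published interaction-model
odds ratios (three GRS×SEP models' RERIs), and additionally exercises the
full simulate–fit pipeline at study scale with the given seed. Results are
written as JSON to `--out`.

## Methods

See `docs/methods.md` for the model, the generator's assumptions, numerical
choices and known limitations.
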