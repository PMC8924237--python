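"""Synthetic cohort generator.

Emulates the statistical structure of a population-based screening cohort in
which a binary outcome (MGUS status) depends on age, sex, an unweighted
genetic risk allele sum score (GRS) and a socioeconomic-position (SEP)
indicator, with a GRS×SEP product term:

    logit P(Y=1) = b0 + b_age·age + b_sex·male + b_grs·GRS
                   + b_sep·SEP + b_int·GRS·SEP

Genotypes are drawn under Hardy–Weinberg equilibrium per SNP; proxy markers
are generated at a controlled LD r² by simulating two-locus haplotypes with
the coefficient of disequilibrium D chosen so r² = D²/(p₁q₁p₂q₂) hits the
target, then collapsing haplotype pairs to genotype dosages.

Default generative parameters reproduce the published study's stated world:
n = 4329 participants aged 45–75, ~5.5% outcome prevalence, a 10-SNP panel
whose allele frequencies give a GRS of mean ≈ 5.3 and sd ≈ 2.0, one proxy
pair at r² = 0.86, education/income/risk-factor marginals near the printed
cohort characteristics, and log-odds effects equal to the published
interaction-model estimates (per-allele OR 1.01, high-SEP OR 0.58,
interaction OR 1.17, age OR 1.04/yr, male OR 1.39). Genotype and SEP are
generated independently (the standard G×E null structure); the intercept is
calibrated deterministically to the target prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .grs import PanelEntry, SnpPanel, compute_grs
from .sep import FFQ_LEVELS, code_education, equivalize_income, sex_specific_quantiles

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "make_panel",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_outcome",
    "simulate_cohort",
    "calibrate_intercept",
    "write_fixture",
    "config_grs2019",
]

# Risk allele frequencies chosen so the 10-SNP score matches the published
# score moments (mean 5.3, sd 2.0). Risk alleles need not be minor.
_DEFAULT_MAFS = (0.10, 0.15, 0.18, 0.22, 0.25, 0.28, 0.30, 0.33, 0.39, 0.45)

# Second panel: frequencies averaging 0.45 -> score mean 9.0, sd 2.0.
_MAFS_2019 = (0.15, 0.20, 0.30, 0.40, 0.55, 0.60, 0.65, 0.70, 0.75, 0.20)

_DEFAULT_EDUCATION = {
    8: 0.010, 9: 0.020, 10: 0.083,          # <=10 band: 11.3%
    11: 0.150, 12: 0.200, 13: 0.208,        # 11-13 band: 55.8%
    14: 0.070, 15: 0.060, 16: 0.050, 17: 0.045,  # 14-17 band: 22.5%
    18: 0.050, 19: 0.025, 20: 0.015, 21: 0.010, 22: 0.004,  # >=18: 10.4%
}

_DEFAULT_WEIGHTS = {1.0: 0.25, 1.5: 0.45, 2.1: 0.20, 2.8: 0.10}

_DEFAULT_RF_PREV = {
    "smoking_ever": 0.58,
    "obesity": 0.27,
    "diabetes": 0.136,
    "low_fish": 0.63,
    "low_boiled_veg": 0.63,
    "low_raw_veg": 0.69,
    "low_fruit": 0.31,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of one synthetic cohort.

    The same config (including seed) always yields a bit-identical cohort.
    ``beta_intercept=None`` calibrates the intercept so the expected
    prevalence equals ``target_prevalence``.
    """

    n_participants: int = 4329
    seed: int = 0
    snp_mafs: tuple[float, ...] = _DEFAULT_MAFS
    #: (snp_index, target_r2) or (snp_index, target_r2, proxy_freq)
    proxy_pairs: tuple[tuple, ...] = ((0, 0.86),)
    age_range: tuple[float, float] = (45.0, 75.0)
    female_fraction: float = 0.5
    education_years_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_EDUCATION)
    )
    income_lognormal_params: tuple[float, float] = (7.71, 0.25)  # (mu, sigma), €/month
    household_weight_distribution: dict[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    risk_factor_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RF_PREV)
    )
    beta_intercept: float | None = None
    target_prevalence: float = 0.055
    beta_age: float = math.log(1.04)      # per year
    beta_sex: float = math.log(1.39)      # male vs female
    beta_grs: float = math.log(1.01)      # per risk allele
    beta_sep: float = math.log(0.58)      # high vs low SEP
    beta_interaction: float = math.log(1.17)
    sep_indicator: str = "education"      # or "income"
    #: opt-in missingness: column name -> fraction masked
    missing_fractions: dict[str, float] = field(default_factory=dict)
    panel_name: str = "GRS_panelA"

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for p in self.snp_mafs:
            if not 0.0 < p < 1.0:
                raise ValueError(f"allele frequency {p} outside (0, 1)")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.sep_indicator not in ("education", "income"):
            raise ValueError("sep_indicator must be 'education' or 'income'")
        for pair in self.proxy_pairs:
            idx, r2 = pair[0], pair[1]
            if not 0 <= idx < len(self.snp_mafs):
                raise ValueError(f"proxy snp_index {idx} out of range")
            if not 0.0 < r2 <= 1.0:
                raise ValueError(f"target r2 {r2} outside (0, 1]")
        for name, frac in self.missing_fractions.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"missing fraction for {name} outside [0, 1)")

    @property
    def snp_ids(self) -> list[str]:
        return [f"snp{i + 1:02d}" for i in range(len(self.snp_mafs))]


def config_grs2019(**overrides) -> SimulationConfig:
    """Config variant emulating the second published panel (score mean ≈ 9.0,
    one proxy at r² = 0.73)."""
    base = dict(
        snp_mafs=_MAFS_2019,
        proxy_pairs=((0, 0.73),),
        panel_name="GRS_panelB",
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticCohort:
    """Genotype dosage matrix + phenotype table + the panel that scores it."""

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    panel: SnpPanel
    config: SimulationConfig


def make_panel(config: SimulationConfig) -> SnpPanel:
    """Panel definition matching the simulated genotype columns.

    Simulated dosages count allele "A" (the risk allele); proxy columns are
    named ``<rsid>_px``.
    """
    proxied = {pair[0] for pair in config.proxy_pairs}
    entries = []
    for i, rsid in enumerate(config.snp_ids):
        if i in proxied:
            r2 = next(p[1] for p in config.proxy_pairs if p[0] == i)
            entries.append(
                PanelEntry(rsid, "A", proxy_rsid=f"{rsid}_px", proxy_r2=r2,
                           proxy_risk_allele="A")
            )
        else:
            entries.append(PanelEntry(rsid, "A"))
    return SnpPanel(name=config.panel_name, entries=tuple(entries))


def _haplotype_pair(
    rng: np.random.Generator, n: int, p1: float, p2: float, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dosages at two loci with squared allelic correlation ``r2``.

    Two-locus haplotype frequencies use D = sqrt(r2·p1·q1·p2·q2) (positive
    phase: the risk alleles co-occur); each individual is two multinomial
    haplotype draws.
    """
    q1, q2 = 1.0 - p1, 1.0 - p2
    d_max = min(p1 * q2, q1 * p2)
    d = math.sqrt(r2 * p1 * q1 * p2 * q2)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (p1 * q1 * p2 * q2)
        raise ValueError(
            f"target r2={r2} infeasible for allele frequencies ({p1}, {p2}); "
            f"maximum attainable r2 is {r2_max:.4f}"
        )
    probs = np.array(
        [p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d]
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    hap = rng.multinomial(2, probs, size=n)  # counts of (AB, Ab, aB, ab)
    dos1 = hap[:, 0] + hap[:, 1]
    dos2 = hap[:, 0] + hap[:, 2]
    return dos1.astype(float), dos2.astype(float)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the samples × SNPs dosage matrix (plus ``*_px`` proxy columns).

    Each SNP is Binomial(2, freq) under HWE; proxy pairs are generated at
    the configured haplotype-level r².
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_participants
    proxy_by_idx = {pair[0]: pair for pair in config.proxy_pairs}
    cols: dict[str, np.ndarray] = {}
    for i, (rsid, maf) in enumerate(zip(config.snp_ids, config.snp_mafs)):
        if i in proxy_by_idx:
            pair = proxy_by_idx[i]
            proxy_freq = pair[2] if len(pair) > 2 else maf
            d1, d2 = _haplotype_pair(rng, n, maf, proxy_freq, pair[1])
            cols[rsid] = d1
            cols[f"{rsid}_px"] = d2
        else:
            cols[rsid] = rng.binomial(2, maf, size=n).astype(float)
    index = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(cols, index=index)


def _ffq_column(
    rng: np.random.Generator, n: int, low_prev: float, fish_style: bool
) -> np.ndarray:
    """Five-level FFQ categories with P(low consumption) = ``low_prev``.

    Vegetables/fruit are "low" from the 1-3 times/week level down; fish is
    "low" from 1-3 times/month down. Within the high/low halves the relative
    level proportions are fixed.
    """
    if fish_style:
        high_split = np.array([0.05, 0.20, 0.75])  # daily .. 1-3/week
        low_split = np.array([0.70, 0.30])         # 1-3/month, never
    else:
        high_split = np.array([0.40, 0.60])        # daily, 4-6/week
        low_split = np.array([0.60, 0.30, 0.10])   # 1-3/week .. never
    probs = np.concatenate([(1 - low_prev) * high_split, low_prev * low_split])
    idx = rng.choice(len(FFQ_LEVELS), size=n, p=probs)
    return np.array(FFQ_LEVELS)[idx]


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw age, sex, SEP raw fields and raw risk-factor fields."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_participants
    prev = config.risk_factor_prevalences

    age = rng.uniform(*config.age_range, size=n)
    male = (rng.random(n) >= config.female_fraction).astype(float)

    edu_years = np.array(sorted(config.education_years_distribution))
    edu_probs = np.array(
        [config.education_years_distribution[y] for y in edu_years], dtype=float
    )
    edu_probs /= edu_probs.sum()
    education_years = rng.choice(edu_years, size=n, p=edu_probs).astype(float)

    mu, sigma = config.income_lognormal_params
    household_income = rng.lognormal(mu, sigma, size=n)
    weights = np.array(sorted(config.household_weight_distribution))
    w_probs = np.array(
        [config.household_weight_distribution[w] for w in weights], dtype=float
    )
    w_probs /= w_probs.sum()
    household_weight = rng.choice(weights, size=n, p=w_probs)

    smoking_ever = (rng.random(n) < prev["smoking_ever"]).astype(float)

    # BMI normal with sd 4.6; mean set so P(BMI >= 30) matches the target.
    bmi_mu = 30.0 - 4.6 * norm.ppf(1.0 - prev["obesity"])
    bmi = rng.normal(bmi_mu, 4.6, size=n)

    fasting = (rng.random(n) < 0.7).astype(float)
    glucose = np.where(
        fasting == 1.0, rng.normal(100.0, 18.0, n), rng.normal(140.0, 35.0, n)
    )
    # glucose criteria alone give ~7% prevalence; history tops up the union
    p_glu = 0.7 * (1 - norm.cdf(125.0, 100.0, 18.0)) + 0.3 * (
        1 - norm.cdf(200.0, 140.0, 35.0)
    )
    p_hist = max(0.0, 1.0 - (1.0 - prev["diabetes"]) / (1.0 - p_glu))
    diabetes_history = (rng.random(n) < p_hist).astype(float)
    glucose_drugs = diabetes_history * (rng.random(n) < 0.5).astype(float)

    df = pd.DataFrame(
        {
            "age": age,
            "male": male,
            "education_years": education_years,
            "household_income": household_income,
            "household_weight": household_weight,
            "smoking_ever": smoking_ever,
            "bmi": bmi,
            "glucose": glucose,
            "fasting": fasting,
            "diabetes_history": diabetes_history,
            "glucose_drugs": glucose_drugs,
            "ffq_fish": _ffq_column(rng, n, prev["low_fish"], fish_style=True),
            "ffq_boiled_veg": _ffq_column(rng, n, prev["low_boiled_veg"], False),
            "ffq_raw_veg": _ffq_column(rng, n, prev["low_raw_veg"], False),
            "ffq_fruit": _ffq_column(rng, n, prev["low_fruit"], False),
        },
        index=pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id"),
    )
    return df


def _linear_predictor_terms(
    cohort: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Everything except the intercept."""
    grs = cohort["grs"].to_numpy(float)
    sep = cohort["sep_high"].to_numpy(float)
    return (
        config.beta_age * cohort["age"].to_numpy(float)
        + config.beta_sex * cohort["male"].to_numpy(float)
        + config.beta_grs * grs
        + config.beta_sep * sep
        + config.beta_interaction * grs * sep
    )


def calibrate_intercept(lp_terms: np.ndarray, target_prevalence: float) -> float:
    """Intercept b0 so that mean(expit(b0 + lp)) equals the target prevalence.

    Deterministic given the covariates; solved by bracketing root finding.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    if lp_terms.size == 0:
        return float(logit(target_prevalence))

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp_terms))) - target_prevalence

    lo = float(logit(target_prevalence) - np.max(lp_terms) - 1.0)
    hi = float(logit(target_prevalence) - np.min(lp_terms) + 1.0)
    return float(brentq(gap, lo, hi, xtol=1e-12))


def simulate_outcome(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Bernoulli outcome from the logistic generative model.

    ``cohort`` must already carry ``grs`` and ``sep_high`` columns (the
    generative model acts on the coded scales, exactly as the analysis
    models do).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    lp = _linear_predictor_terms(cohort, config)
    b0 = (
        config.beta_intercept
        if config.beta_intercept is not None
        else calibrate_intercept(lp, config.target_prevalence)
    )
    prob = expit(b0 + lp)
    y = (rng.random(len(cohort)) < prob).astype(int)
    return pd.Series(y, index=cohort.index, name="mgus")


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full generative pipeline: genotypes → GRS → covariates → SEP → outcome.

    The phenotype table contains the raw fields a study export would carry
    (the analysis re-derives SEP and risk-factor codes from them) plus the
    outcome. The generative SEP is the coded indicator named by
    ``config.sep_indicator``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_out, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    genotypes = simulate_genotypes(config, rng_geno)
    covars = simulate_covariates(config, rng_cov)
    panel = make_panel(config)

    cohort = covars.copy()
    cohort["grs"] = compute_grs(genotypes, panel).score

    if config.sep_indicator == "education":
        cohort["sep_high"] = code_education(cohort["education_years"])["education_high"]
    else:
        eq = equivalize_income(cohort["household_income"], cohort["household_weight"])
        cohort["sep_high"] = sex_specific_quantiles(eq, cohort["male"])["income_high"]

    cohort["mgus"] = simulate_outcome(cohort, config, rng_out)

    phenotypes = covars.copy()
    phenotypes.insert(0, "mgus", cohort["mgus"])

    for col, frac in config.missing_fractions.items():
        if col in phenotypes.columns and frac > 0:
            mask = rng_miss.random(len(phenotypes)) < frac
            phenotypes.loc[mask, col] = np.nan

    return SyntheticCohort(
        genotypes=genotypes, phenotypes=phenotypes, panel=panel, config=config
    )


def write_fixture(
    cohort: SyntheticCohort,
    genotype_path: str | Path,
    phenotype_path: str | Path,
    panel_path: str | Path | None = None,
) -> None:
    """Write the cohort as a dosage TSV + phenotype CSV (+ panel TSV).

    Output round-trips losslessly through the :mod:`gxsep.io` readers and is
    byte-identical for identical configs.
    """
    cohort.genotypes.to_csv(genotype_path, sep="\t", float_format="%.6g")
    cohort.phenotypes.to_csv(phenotype_path, float_format="%.10g")
    if panel_path is not None:
        rows = []
        for e in cohort.panel.entries:
            rows.append(
                {
                    "rsid": e.rsid,
                    "risk_allele": e.risk_allele,
                    "proxy_rsid": e.proxy_rsid or "",
                    "proxy_r2": "" if e.proxy_r2 is None else e.proxy_r2,
                    "proxy_risk_allele": e.proxy_risk_allele or "",
                }
            )
        pd.DataFrame(rows).to_csv(panel_path, sep="\t", index=False)
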