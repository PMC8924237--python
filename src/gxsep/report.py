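"""End-to-end analysis driver and table rendering.

``run_analysis`` ties the modules together: score the panel, code the SEP
indicators and risk factors, then fit every analysis stage (main effects,
SEP-stratified GRS effects, interaction models with RERI, single-reference
joint effects, risk-factor-extended models, and the per-SNP scan). The
result is a :class:`ResultsBundle` carrying every fitted table plus
provenance (config digest, per-model n / n_case / exclusions), serialisable
to JSON with full precision; ``render_tables`` writes deterministic CSV and
Markdown views with journal-style formatting (2-decimal ORs,
"0.10 (0.05; 0.14)" cells, scientific notation for small p-values).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .grs import SnpPanel, compute_grs, tertiles
from .io import AnalysisConfig
from .models import (
    InteractionResult,
    extended_interaction_model,
    interaction_model,
    joint_effects,
    main_effect_models,
    single_snp_scan,
    stratified_effects,
)
from .sep import code_education, code_risk_factors, equivalize_income, sex_specific_quantiles

__all__ = ["ResultsBundle", "prepare_cohort", "run_analysis", "render_tables"]

RISK_FACTORS = (
    "smoking_ever",
    "obesity",
    "diabetes",
    "low_fish",
    "low_boiled_veg",
    "low_raw_veg",
    "low_fruit",
)


@dataclass
class ResultsBundle:
    """All fitted tables of one analysis run, with provenance."""

    main_effects: pd.DataFrame
    stratified: dict[str, pd.DataFrame]
    interactions: dict[str, InteractionResult]
    joint: dict[str, pd.DataFrame]
    extended: pd.DataFrame
    snp_scan: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def enc(obj):
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="split"))
            if isinstance(obj, InteractionResult):
                d = {
                    k: v
                    for k, v in asdict(obj).items()
                    if k != "fit"
                }
                d["fit"] = {
                    "params": obj.fit.params.to_dict(),
                    "vcov": obj.fit.vcov.to_dict(),
                    "n": obj.fit.n,
                    "n_case": obj.fit.n_case,
                    "n_excluded": obj.fit.n_excluded,
                    "converged": obj.fit.converged,
                    "llf": obj.fit.llf,
                    "description": obj.fit.description,
                }
                return d
            raise TypeError(type(obj))

        payload = {
            "provenance": self.provenance,
            "main_effects": enc(self.main_effects),
            "stratified": {k: enc(v) for k, v in self.stratified.items()},
            "interactions": {k: enc(v) for k, v in self.interactions.items()},
            "joint": {k: enc(v) for k, v in self.joint.items()},
            "extended": enc(self.extended),
            "snp_scan": enc(self.snp_scan) if self.snp_scan is not None else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def prepare_cohort(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    allele_info: Mapping | None = None,
) -> pd.DataFrame:
    """Derive the coded analysis frame from raw inputs.

    Adds GRS + tertiles, education categories/binary, equivalised income
    with sex-specific quartile and median-split labels, and the
    dichotomised risk factors, keeping the raw columns.
    """
    df = phenotypes.copy()
    res = compute_grs(genotypes, panel, allele_info=allele_info)
    df["grs"] = res.score
    df["grs_n_proxied"] = res.n_proxied
    df["grs_tertile"] = tertiles(res.score)

    if "education_years" in df:
        edu = code_education(df["education_years"])
        df["education_cat4"] = edu["education_cat4"]
        df["education_high"] = edu["education_high"]
    if "household_income" in df and "household_weight" in df:
        df["equivalized_income"] = equivalize_income(
            df["household_income"], df["household_weight"]
        )
        inc = sex_specific_quantiles(df["equivalized_income"], df["male"])
        df["income_quartile"] = inc["income_quartile"]
        df["income_high"] = inc["income_high"]
    rf = code_risk_factors(df)
    for col in rf.columns:
        df[col] = rf[col]
    return df


def run_analysis(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    config: AnalysisConfig | None = None,
    allele_info: Mapping | None = None,
) -> ResultsBundle:
    """Execute every analysis stage on one cohort and one panel."""
    config = config or AnalysisConfig()
    df = prepare_cohort(phenotypes, genotypes, panel, allele_info)

    sep_cols = [c for c in ("education_high", "income_high") if c in df]
    main = main_effect_models(df, exposures=["grs", *sep_cols])

    strat = {}
    if "education_cat4" in df:
        strat["education"] = stratified_effects(df, strata="education_cat4")
    if "income_quartile" in df:
        strat["income"] = stratified_effects(df, strata="income_quartile")

    inter = {}
    for name, col in (("education", "education_high"), ("income", "income_high")):
        if col in df:
            inter[name] = interaction_model(
                df, sep=col, grs_increment=config.grs_increment,
                ci_method=config.ci_method, n_boot=config.bootstrap_reps,
                seed=config.seed,
            )

    joint = {}
    if "education_cat4" in df:
        joint["education"] = joint_effects(df, sep="education_cat4")
    if "income_quartile" in df:
        joint["income"] = joint_effects(df, sep="income_quartile")

    sep_main = (
        "education_high" if config.sep_indicator == "education" else "income_high"
    )
    ext_rows = []
    base = inter.get(config.sep_indicator)
    if base is not None:
        ext_rows.append(_extended_row("base model", base))
        for rf in RISK_FACTORS:
            if rf in df and df[rf].notna().any():
                res = extended_interaction_model(
                    df, risk_factor=rf, sep=sep_main,
                    grs_increment=config.grs_increment,
                )
                ext_rows.append(_extended_row(rf, res))
    extended = pd.DataFrame(ext_rows).set_index("model") if ext_rows else pd.DataFrame()

    snp_scan = None
    if base is not None:
        snp_cols = [r for r in panel.rsids if r in genotypes.columns]
        scan_df = df.join(genotypes[snp_cols])
        snp_scan = single_snp_scan(
            scan_df, snp_cols, sep=sep_main,
            reference_sign=float(np.sign(np.log(base.or_interaction))),
        )

    provenance = {
        "gxsep_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "panel": panel.name,
        "n_samples": int(len(df)),
        "n_cases": int(pd.to_numeric(df["mgus"], errors="coerce").sum()),
        "per_model_n": {
            **{f"main:{k}": int(v) for k, v in main["n"].items()},
            **{f"interaction:{k}": v.n for k, v in inter.items()},
        },
    }
    return ResultsBundle(
        main_effects=main,
        stratified=strat,
        interactions=inter,
        joint=joint,
        extended=extended,
        snp_scan=snp_scan,
        provenance=provenance,
    )


def _extended_row(name: str, res: InteractionResult) -> dict:
    return {
        "model": name,
        "n": res.n,
        "n_case": res.n_case,
        "or_interaction": res.or_interaction,
        "or_ci_low": res.or_ci[0],
        "or_ci_high": res.or_ci[1],
        "p_interaction": res.p_interaction,
        "reri": res.reri,
        "reri_ci_low": res.reri_ci[0],
        "reri_ci_high": res.reri_ci[1],
    }


def fmt_est_ci(est: float, lo: float, hi: float) -> str:
    """Journal-style "1.17 (1.03; 1.33)" cell."""
    if not np.isfinite(est):
        return "inestimable"
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return f"{est:.2f}"
    return f"{est:.2f} ({lo:.2f}; {hi:.2f})"


def fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 1e-3:
        return f"{p:.2e}"
    return f"{p:.2f}"


def render_tables(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write CSV tables plus a Markdown summary; deterministic ordering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p)
        written.append(p)

    save(bundle.main_effects, "main_effects.csv")
    for k, v in bundle.stratified.items():
        save(v, f"stratified_{k}.csv")  # forest-plot data: OR + CI per stratum
    for k, v in bundle.joint.items():
        save(v, f"joint_effects_{k}.csv")
    if len(bundle.extended):
        save(bundle.extended, "extended_models.csv")
    if bundle.snp_scan is not None:
        save(bundle.snp_scan, "snp_scan.csv")

    inter_rows = []
    for k, v in bundle.interactions.items():
        inter_rows.append(
            {
                "sep_indicator": k,
                "n": v.n,
                "n_case": v.n_case,
                "or_interaction": v.or_interaction,
                "or_ci_low": v.or_ci[0],
                "or_ci_high": v.or_ci[1],
                "p_interaction": v.p_interaction,
                "reri": v.reri,
                "reri_ci_low": v.reri_ci[0],
                "reri_ci_high": v.reri_ci[1],
                "ci_method": v.ci_method,
            }
        )
    if inter_rows:
        save(pd.DataFrame(inter_rows).set_index("sep_indicator"), "interactions.csv")

    md = ["# Analysis summary", ""]
    md.append("## Main effects (age- and sex-adjusted)")
    for term, row in bundle.main_effects.iterrows():
        md.append(
            f"- {term}: OR {fmt_est_ci(row['or'], row['ci_low'], row['ci_high'])}, "
            f"p = {fmt_p(row['p'])}, n = {row['n']} ({row['n_case']} cases)"
        )
    md.append("")
    for k, v in bundle.interactions.items():
        md.append(f"## GRS x {k} interaction")
        md.append(
            f"- multiplicative OR {fmt_est_ci(v.or_interaction, *v.or_ci)}, "
            f"p = {fmt_p(v.p_interaction)}"
        )
        md.append(f"- RERI {fmt_est_ci(v.reri, *v.reri_ci)} [{v.ci_method}]")
        md.append(f"- n = {v.n} ({v.n_case} cases)")
        md.append("")
    for k, v in bundle.stratified.items():
        md.append(f"## GRS effect stratified by {k}")
        for stratum, row in v.iterrows():
            if not row.get("estimable", True) or not np.isfinite(row["or"]):
                md.append(f"- {stratum}: inestimable (n = {row['n']})")
            else:
                md.append(
                    f"- {stratum}: OR {fmt_est_ci(row['or'], row['ci_low'], row['ci_high'])} "
                    f"(n = {row['n']})"
                )
        md.append("")
    p = outdir / "summary.md"
    p.write_text("\n".join(md))
    written.append(p)
    bundle.to_json(outdir / "results_bundle.json")
    written.append(outdir / "results_bundle.json")
    return written
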