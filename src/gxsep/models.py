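"""Logistic models and interaction contrasts (multiplicative OR and RERI).

The analysis pipeline mirrors a four-stage gene–environment interaction
design:

1. main-effect models — age- and sex-adjusted logistic regression for each
   GRS and each dichotomised SEP indicator separately;
2. interaction models — outcome ~ age + sex + GRS + SEP + GRS×SEP, giving
   the multiplicative interaction OR and, from the same fit, the relative
   excess risk due to interaction (RERI) on the additive scale;
3. single-reference joint effects — GRS tertile × SEP category dummies in
   one model against the (lowest GRS, lowest SEP) reference cell;
4. risk-factor-extended models — the base interaction model plus risk-factor
   main effect and GRS×RF, SEP×RF product terms, to check whether a
   candidate risk factor accounts for the GRS×SEP interaction.

RERI for exposures G (continuous, per increment c) and S (binary) from a
logistic fit with coefficients b_g, b_s, b_int is

    RERI = exp(c·b_g + b_s + c·b_int) − exp(c·b_g) − exp(b_s) + 1,

zero when risks combine additively. Its 95% CI uses the delta method on the
three-coefficient gradient (the standard Hosmer–Lemeshow approach); a
percentile bootstrap over refitted resamples is available as a cross-check.

All CIs are Wald (exp(b ± 1.96·SE)); no multiple-testing adjustment is
applied anywhere. Complete-case exclusion is per model, never global.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "LogisticFit",
    "InteractionResult",
    "fit_logistic",
    "compute_reri",
    "interaction_model",
    "main_effect_models",
    "stratified_effects",
    "joint_effects",
    "extended_interaction_model",
    "single_snp_scan",
]

Z95 = norm.ppf(0.975)
SEPARATION_BOUND = 15.0  # |log-odds| beyond this flags separation


class SingleClassError(ValueError):
    """Outcome has only one class; a logistic model cannot be fitted."""


@dataclass
class LogisticFit:
    """One fitted logistic regression: estimates, vcov and bookkeeping."""

    params: pd.Series
    vcov: pd.DataFrame
    n: int
    n_case: int
    n_excluded: int
    converged: bool
    llf: float
    description: str = ""

    def or_table(self) -> pd.DataFrame:
        """OR, 95% Wald CI and p-value per non-intercept term."""
        se = pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)
        z = self.params / se
        p = 2 * norm.sf(np.abs(z))
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
                "p": p,
            }
        )
        return tab.drop(index="const", errors="ignore")


@dataclass
class InteractionResult:
    """GRS×SEP contrast from one interaction fit, on both scales."""

    or_interaction: float
    or_ci: tuple[float, float]
    p_interaction: float
    reri: float
    reri_ci: tuple[float, float]
    reri_se: float | None
    grs_term: str
    sep_term: str
    grs_increment: float
    ci_method: str
    fit: LogisticFit
    n: int
    n_case: int


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    description: str = "",
) -> LogisticFit:
    """Maximum-likelihood logistic regression with complete-case exclusion.

    Rows missing the outcome or any term are dropped and counted in
    ``n_excluded``. Convergence and separation (any |coefficient| >
    ``SEPARATION_BOUND``) are reported honestly via ``converged``.
    """
    cols = [outcome, *terms]
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_excluded = len(sub) - len(complete)
    y = complete[outcome].to_numpy(float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise SingleClassError(
            f"outcome {outcome!r} has a single class ({classes}) after "
            "complete-case exclusion"
        )
    X = sm.add_constant(complete[list(terms)].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            # fall back to a damped optimizer; flag non-convergence
            res = model.fit(disp=0, method="bfgs", maxiter=200)
            converged = False
    params = pd.Series(res.params, index=X.columns)
    if np.any(np.abs(params.drop("const")) > SEPARATION_BOUND):
        converged = False
    vcov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return LogisticFit(
        params=params,
        vcov=vcov,
        n=len(complete),
        n_case=int(y.sum()),
        n_excluded=n_excluded,
        converged=converged,
        llf=float(res.llf),
        description=description,
    )


def compute_reri(
    b_g: float,
    b_s: float,
    b_int: float,
    vcov: np.ndarray | pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float | None]:
    """RERI with a delta-method confidence interval.

    Parameters are the log-odds coefficients of the exposure main effects
    and their product term (already scaled to the contrast of interest) and
    the corresponding 3×3 covariance submatrix in order (g, s, int).

    Returns ``(reri, (lo, hi), se)``; with ``vcov=None`` only the point
    estimate is computed and the CI is ``(nan, nan)``.

    RERI = exp(b_g + b_s + b_int) − exp(b_g) − exp(b_s) + 1. The variance is
    gᵀΣg with gradient g = (e^s − e^{b_g}, e^s − e^{b_s}, e^s) where
    s = b_g + b_s + b_int.
    """
    s = b_g + b_s + b_int
    reri = float(np.exp(s) - np.exp(b_g) - np.exp(b_s) + 1.0)
    if vcov is None:
        return reri, (float("nan"), float("nan")), None
    sigma = np.asarray(vcov, dtype=float)
    if sigma.shape != (3, 3):
        raise ValueError("vcov must be the 3x3 (g, s, int) submatrix")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("vcov must be symmetric")
    eigs = np.linalg.eigvalsh(sigma)
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        raise ValueError("vcov is not positive semi-definite")
    grad = np.array(
        [np.exp(s) - np.exp(b_g), np.exp(s) - np.exp(b_s), np.exp(s)]
    )
    var = float(grad @ sigma @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    return reri, (reri - z * se, reri + z * se), se


def _reri_from_fit(
    fit: LogisticFit, grs_term: str, sep_term: str, int_term: str, c: float
) -> tuple[float, tuple[float, float], float | None]:
    """RERI for a GRS increment ``c`` vs the SEP high/low contrast."""
    b = fit.params
    idx = [grs_term, sep_term, int_term]
    sigma = fit.vcov.loc[idx, idx].to_numpy()
    # scaling the GRS contrast by c scales row/col of g and int terms
    scale = np.diag([c, 1.0, c])
    return compute_reri(
        c * b[grs_term], b[sep_term], c * b[int_term], scale @ sigma @ scale
    )


def interaction_model(
    data: pd.DataFrame,
    grs: str = "grs",
    sep: str = "sep_high",
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
    grs_increment: float = 1.0,
    ci_method: str = "delta",
    n_boot: int = 500,
    seed: int | None = None,
    rereference: bool = False,
    extra_terms: Sequence[str] = (),
) -> InteractionResult:
    """Fit outcome ~ covariates + GRS + SEP + GRS×SEP and summarise both scales.

    ``ci_method`` selects the RERI CI: ``"delta"`` (default, deterministic)
    or ``"bootstrap"`` (percentile over ``n_boot`` refitted row resamples;
    needs ``seed``). ``rereference`` flips the SEP coding when its
    main-effect estimate is negative, so RERI is computed against the
    lowest-risk reference (the point estimate changes meaning; a warning is
    issued).
    """
    work = data.copy()
    int_term = f"{grs}_x_{sep}"
    work[int_term] = work[grs] * work[sep]
    terms = [*covariates, grs, sep, int_term, *extra_terms]
    fit = fit_logistic(
        work, outcome, terms, description=f"{outcome} ~ {' + '.join(terms)}"
    )

    if rereference and fit.params[sep] < 0:
        warnings.warn(
            "SEP main effect is protective; re-referencing to the low-risk "
            "category. The RERI now describes the re-referenced contrast and "
            "is not comparable to the default parameterisation.",
            stacklevel=2,
        )
        flipped = data.copy()
        flipped[sep] = 1.0 - flipped[sep].astype(float)
        return interaction_model(
            flipped, grs, sep, covariates, outcome, grs_increment,
            ci_method, n_boot, seed, rereference=False, extra_terms=extra_terms,
        )

    se_int = float(np.sqrt(fit.vcov.loc[int_term, int_term]))
    b_int = float(fit.params[int_term])
    or_int = float(np.exp(grs_increment * b_int))
    ci = (
        float(np.exp(grs_increment * (b_int - Z95 * se_int))),
        float(np.exp(grs_increment * (b_int + Z95 * se_int))),
    )
    p_int = float(2 * norm.sf(abs(b_int / se_int)))

    reri, reri_ci, reri_se = _reri_from_fit(fit, grs, sep, int_term, grs_increment)
    if ci_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        idx = np.arange(len(work))
        for b in range(n_boot):
            take = rng.choice(idx, size=len(idx), replace=True)
            boot = work.iloc[take]
            try:
                bf = fit_logistic(boot, outcome, terms)
                reps[b] = _reri_from_fit(bf, grs, sep, int_term, grs_increment)[0]
            except (SingleClassError, np.linalg.LinAlgError):
                reps[b] = np.nan
        good = reps[~np.isnan(reps)]
        reri_ci = (
            float(np.percentile(good, 2.5)),
            float(np.percentile(good, 97.5)),
        )
        reri_se = float(good.std(ddof=1))
    elif ci_method != "delta":
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    return InteractionResult(
        or_interaction=or_int,
        or_ci=ci,
        p_interaction=p_int,
        reri=reri,
        reri_ci=(float(reri_ci[0]), float(reri_ci[1])),
        reri_se=reri_se,
        grs_term=grs,
        sep_term=sep,
        grs_increment=grs_increment,
        ci_method=ci_method,
        fit=fit,
        n=fit.n,
        n_case=fit.n_case,
    )


def main_effect_models(
    data: pd.DataFrame,
    exposures: Sequence[str] = ("grs", "education_high", "income_high"),
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
) -> pd.DataFrame:
    """One age- and sex-adjusted model per exposure; OR per exposure term.

    Returns a table with one row per exposure: n, n_case, OR, 95% CI, p.
    """
    rows = []
    for term in exposures:
        fit = fit_logistic(
            data, outcome, [*covariates, term],
            description=f"{outcome} ~ {' + '.join([*covariates, term])}",
        )
        tab = fit.or_table().loc[term]
        rows.append(
            {
                "exposure": term,
                "n": fit.n,
                "n_case": fit.n_case,
                "n_excluded": fit.n_excluded,
                "or": tab["or"],
                "ci_low": tab["ci_low"],
                "ci_high": tab["ci_high"],
                "p": tab["p"],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("exposure")


def stratified_effects(
    data: pd.DataFrame,
    grs: str = "grs",
    strata: str = "education_cat4",
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
) -> pd.DataFrame:
    """Per-SEP-stratum GRS effect from independent age/sex-adjusted fits.

    Strata with a single outcome class are flagged (``estimable=False``)
    and the remaining strata are still returned.
    """
    rows = []
    col = data[strata]
    levels = (
        list(col.cat.categories) if hasattr(col, "cat") else sorted(col.dropna().unique())
    )
    for level in levels:
        sub = data[col == level]
        row = {"stratum": level, "n": len(sub.dropna(subset=[outcome]))}
        try:
            fit = fit_logistic(sub, outcome, [*covariates, grs])
            tab = fit.or_table().loc[grs]
            row.update(
                n=fit.n,
                n_case=fit.n_case,
                or_=tab["or"],
                ci_low=tab["ci_low"],
                ci_high=tab["ci_high"],
                p=tab["p"],
                estimable=fit.converged,
            )
        except SingleClassError:
            row.update(
                n_case=int(pd.to_numeric(sub[outcome], errors="coerce").sum()),
                or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                estimable=False,
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("stratum")
    return out.rename(columns={"or_": "or"})


def joint_effects(
    data: pd.DataFrame,
    tertile: str = "grs_tertile",
    sep: str = "education_cat4",
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
) -> pd.DataFrame:
    """Single-reference joint effects of GRS tertile × SEP category.

    All non-reference (tertile, SEP) cells enter one age/sex-adjusted model
    as dummy variables; the reference is (lowest tertile, lowest SEP) with
    OR ≡ 1. Empty cells are marked inestimable and their dummy dropped.
    """
    t_col, s_col = data[tertile], data[sep]
    t_levels = list(t_col.cat.categories) if hasattr(t_col, "cat") else sorted(
        t_col.dropna().unique()
    )
    s_levels = list(s_col.cat.categories) if hasattr(s_col, "cat") else sorted(
        s_col.dropna().unique()
    )
    ref = (t_levels[0], s_levels[0])

    work = data[[outcome, *covariates]].copy()
    y = pd.to_numeric(data[outcome], errors="coerce")
    cells = []
    for s_level in s_levels:
        for t_level in t_levels:
            in_cell = (t_col == t_level) & (s_col == s_level)
            name = f"cell_{s_level}_{t_level}"
            cells.append(
                {
                    "sep": s_level,
                    "tertile": t_level,
                    "dummy": name,
                    "n": int((in_cell & y.notna()).sum()),
                    "n_case": int(y[in_cell].sum()) if in_cell.any() else 0,
                    "is_reference": (t_level, s_level) == ref,
                }
            )
            if (t_level, s_level) != ref:
                work[name] = in_cell.astype(float)
                # rows outside every cell (missing tertile/SEP) drop out
    valid = t_col.notna() & s_col.notna()
    work = work[valid]

    dummies = []
    for c in cells:
        if c["is_reference"]:
            continue
        if c["n"] == 0:
            warnings.warn(f"empty joint-effects cell {c['dummy']}; dummy dropped", stacklevel=2)
            work = work.drop(columns=c["dummy"])
        else:
            dummies.append(c["dummy"])

    fit = fit_logistic(
        work, outcome, [*covariates, *dummies],
        description=f"joint effects {tertile} x {sep}",
    )
    tab = fit.or_table()
    rows = []
    for c in cells:
        row = {
            "sep": c["sep"],
            "tertile": c["tertile"],
            "n": c["n"],
            "n_case": c["n_case"],
            "is_reference": c["is_reference"],
        }
        if c["is_reference"]:
            row.update(or_=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan, estimable=True)
        elif c["dummy"] in tab.index:
            t = tab.loc[c["dummy"]]
            estimable = abs(np.log(t["or"])) < SEPARATION_BOUND if t["or"] > 0 else False
            row.update(
                or_=t["or"], ci_low=t["ci_low"], ci_high=t["ci_high"], p=t["p"],
                estimable=estimable,
            )
        else:
            row.update(or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan, estimable=False)
        rows.append(row)
    out = pd.DataFrame(rows).rename(columns={"or_": "or"})
    out.attrs["fit"] = fit
    return out


def extended_interaction_model(
    data: pd.DataFrame,
    risk_factor: str,
    grs: str = "grs",
    sep: str = "sep_high",
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
    grs_increment: float = 1.0,
) -> InteractionResult:
    """Base interaction model extended by one risk factor's terms.

    Adds the risk factor main effect plus GRS×RF and SEP×RF product terms
    and reports the GRS×SEP interaction (OR and RERI) from the extended
    fit, for comparison against the base model: if the risk factor carries
    the interaction, the GRS×SEP estimate attenuates.
    """
    work = data.copy()
    grs_rf = f"{grs}_x_{risk_factor}"
    sep_rf = f"{sep}_x_{risk_factor}"
    work[grs_rf] = work[grs] * work[risk_factor]
    work[sep_rf] = work[sep] * work[risk_factor]
    return interaction_model(
        work, grs=grs, sep=sep, covariates=covariates, outcome=outcome,
        grs_increment=grs_increment,
        extra_terms=(risk_factor, grs_rf, sep_rf),
    )


def single_snp_scan(
    data: pd.DataFrame,
    snp_cols: Sequence[str],
    sep: str = "sep_high",
    covariates: Sequence[str] = ("age", "male"),
    outcome: str = "mgus",
    reference_sign: float | None = None,
) -> pd.DataFrame:
    """Per-SNP interaction scan under an additive genetic model.

    Each panel SNP's dosage replaces the GRS in the interaction model.
    ``reference_sign`` (e.g. the sign of the GRS-level log interaction OR)
    enables the directional-consistency flags; monomorphic SNPs are skipped
    with ``estimable=False``.
    """
    rows = []
    for snp in snp_cols:
        dos = pd.to_numeric(data[snp], errors="coerce")
        if dos.dropna().nunique() < 2:
            rows.append(
                {
                    "snp": snp, "or_interaction": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan, "reri": np.nan,
                    "reri_ci_low": np.nan, "reri_ci_high": np.nan,
                    "estimable": False, "consistent_mult": pd.NA,
                    "consistent_add": pd.NA,
                }
            )
            continue
        res = interaction_model(
            data, grs=snp, sep=sep, covariates=covariates, outcome=outcome
        )
        row = {
            "snp": snp,
            "or_interaction": res.or_interaction,
            "ci_low": res.or_ci[0],
            "ci_high": res.or_ci[1],
            "p": res.p_interaction,
            "reri": res.reri,
            "reri_ci_low": res.reri_ci[0],
            "reri_ci_high": res.reri_ci[1],
            "estimable": res.fit.converged,
            "consistent_mult": pd.NA,
            "consistent_add": pd.NA,
        }
        if reference_sign is not None:
            row["consistent_mult"] = bool(
                np.sign(np.log(res.or_interaction)) == np.sign(reference_sign)
            )
            row["consistent_add"] = bool(np.sign(res.reri) == np.sign(reference_sign))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("snp")
    if reference_sign is not None:
        out.attrs["n_consistent_mult"] = int(
            out["consistent_mult"].fillna(False).astype(bool).sum()
        )
        out.attrs["n_consistent_add"] = int(
            out["consistent_add"].fillna(False).astype(bool).sum()
        )
    return out
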