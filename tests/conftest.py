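import numpy as np
import pandas as pd
import pytest

from gxsep import SimulationConfig, simulate_cohort
from gxsep.report import prepare_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale synthetic cohort (n = 4329) reused across tests."""
    return simulate_cohort(SimulationConfig(seed=12345))


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    """The coded analysis frame for the default cohort."""
    c = default_cohort
    return prepare_cohort(c.phenotypes, c.genotypes, c.panel)


def quick_frame(n: int, seed: int, **config_overrides) -> pd.DataFrame:
    """Simulate and minimally code a cohort for replicate loops.

    Returns a frame with mgus, age, male, grs and sep_high (the generative
    SEP indicator), skipping the risk-factor / income coding that replicate
    tests do not use.
    """
    from gxsep.grs import compute_grs
    from gxsep.sep import code_education, equivalize_income, sex_specific_quantiles

    cfg = SimulationConfig(n_participants=n, seed=seed, **config_overrides)
    c = simulate_cohort(cfg)
    df = c.phenotypes.copy()
    df["grs"] = compute_grs(c.genotypes, c.panel).score
    if cfg.sep_indicator == "education":
        df["sep_high"] = code_education(df["education_years"])["education_high"]
    else:
        eq = equivalize_income(df["household_income"], df["household_weight"])
        df["sep_high"] = sex_specific_quantiles(eq, df["male"])["income_high"]
    return df
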