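import numpy as np
import pandas as pd
import pytest

import pathprs
from pathprs.simulate import SnpSpec


def small_panel(n_snps=12, maf=0.3, block_size=4):
    return tuple(
        SnpSpec(f"s{i:02d}", f"g{i // block_size}", maf, i // block_size)
        for i in range(n_snps)
    )


def null_config(seed, n_cohort=4000, subcohort=1000, **kw):
    """Desk-scale case-cohort generator config with all true effects zero."""
    defaults = dict(
        n_cohort=n_cohort,
        subcohort_size=subcohort,
        snp_spec=small_panel(),
        baseline_hazard=0.004,
        missing_rate_snp=0.0,
        sample_dropout_rate=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return pathprs.SimulationConfig(**defaults)


def toy_case_cohort(seed=0, n=400, subcohort=150, beta_x=0.0, rate=0.02):
    """Minimal analysis table with one covariate and exact PH structure."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    age = rng.uniform(55, 69, n)
    t = rng.exponential(1.0 / (rate * np.exp(beta_x * x)))
    event = (t <= 20.3).astype(int)
    df = pd.DataFrame(
        dict(
            id=np.arange(n),
            sex=np.where(rng.random(n) < 0.5, "male", "female"),
            x=x,
            age_years=age,
            time_years=np.minimum(t, 20.3),
            event=event,
            subsite=np.where(event == 1, "rectum", "none"),
            subcohort=0,
        )
    )
    sub = rng.choice(n, subcohort, replace=False)
    df.loc[sub, "subcohort"] = 1
    return df[(df.subcohort == 1) | (df.event == 1)].reset_index(drop=True)


@pytest.fixture(scope="session")
def built_score():
    """One full score construction shared across tests (null genotypes)."""
    cfg = null_config(seed=11, missing_rate_snp=0.02, sample_dropout_rate=0.02)
    rows, geno = pathprs.simulate_case_cohort(cfg)
    scored, model = pathprs.build_prs(rows, geno, seed=17)
    return rows, geno, scored, model
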