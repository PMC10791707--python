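import numpy as np
import pandas as pd
import pytest

from stratmr import (
    Cohort,
    ExposureSpec,
    OutcomeSpec,
    SimulationConfig,
    ThetaSpec,
    VariantSpec,
    demo_simulation_config,
    simulate_cohort,
)

COVARIATES = ["age", "sex", "pc1", "pc2"]


@pytest.fixture(scope="session")
def demo_cohort():
    """Mid-sized demo cohort shared by read-only tests."""
    cfg = demo_simulation_config(n_individuals=8000, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture()
def noiseless_config():
    """Exposure exactly equals intercept + sum(beta * dosage); no covariates."""
    return SimulationConfig(
        n_individuals=500,
        variants=[
            VariantSpec(id="v1", maf=0.3, beta=0.5),
            VariantSpec(id="v2", maf=0.2, beta=-0.2),
        ],
        exposure=ExposureSpec(intercept=5.0, noise_sd=0.0, confounder_effect=0.0),
        seed=13,
    )


def tiny_cohort(genotypes: dict, phenotypes: dict) -> Cohort:
    """Hand-built cohort from plain dict columns (row-aligned)."""
    n = len(next(iter(genotypes.values())))
    idx = pd.Index([f"I{i:03d}" for i in range(n)], name="iid")
    return Cohort(
        genotypes=pd.DataFrame(genotypes, index=idx),
        phenotypes=pd.DataFrame(phenotypes, index=idx),
    )
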