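import numpy as np
import pandas as pd
import pytest

from stockadmix.synthdata import GenotypeScenario, LakeScenario, generate_genotypes, generate_lake_table


@pytest.fixture(scope="session")
def lake_table_29() -> pd.DataFrame:
    """A 29-lake covariate table drawn from a known regression structure."""
    scenario = LakeScenario(
        n_lakes=29,
        coefficients={"SinceMeanYear": -0.44, "MeanFishStock": 0.30},
        intercept=-2.4,
        precision=20.0,
        seed=42,
    )
    return generate_lake_table(scenario)


@pytest.fixture(scope="session")
def admixed_panel():
    """Genotypes for 60 individuals at 500 loci with known ancestry fractions."""
    scenario = GenotypeScenario(
        n_wild=40,
        n_domestic_ref=20,
        n_loci=500,
        divergence=0.5,
        missing_rate=0.0,
        seed=7,
    )
    return generate_genotypes(scenario)
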