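import numpy as np
import pandas as pd
import pytest

from famliab import (
    LiabilityParams,
    PhenotypeParams,
    simulate_phenotypes,
    simulate_trio_cohort,
)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Unascertained cohort: segregation null holds for every child."""
    params = LiabilityParams(n_families=4000, seed=101, ascertain="none")
    return simulate_trio_cohort(params)


@pytest.fixture(scope="session")
def ascertained_cohort() -> pd.DataFrame:
    """Proband-ascertained cohort at the default study conditions."""
    params = LiabilityParams(n_families=150000, seed=202)
    return simulate_trio_cohort(params)


@pytest.fixture(scope="session")
def phenotyped_probands(null_cohort) -> pd.DataFrame:
    probands = null_cohort[null_cohort["role"] == "proband"]
    return simulate_phenotypes(probands, PhenotypeParams(), seed=303)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
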