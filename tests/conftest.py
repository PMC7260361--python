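import numpy as np
import pandas as pd
import pytest

from dictyfit import survival as surv
from dictyfit import synthetic as syn


@pytest.fixture(scope="session")
def survival_table() -> pd.DataFrame:
    return syn.gen_survival(syn.SurvivalSimConfig(seed=0))


@pytest.fixture(scope="session")
def fitness_table(survival_table) -> pd.DataFrame:
    return surv.relative_fitness(surv.survival_fractions(survival_table))


@pytest.fixture(scope="session")
def morphometry_table() -> pd.DataFrame:
    return syn.gen_morphometry(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
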