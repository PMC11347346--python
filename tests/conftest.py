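import numpy as np
import pandas as pd
import pytest

from fracsurv.cohort import CohortSpec, sample_cohort
from fracsurv.forest import ForestConfig, fit_survival_forest


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """1,200-patient default cohort shared across test modules."""
    return sample_cohort(CohortSpec(n_patients=1200, seed=7))


@pytest.fixture(scope="session")
def small_forest(small_cohort):
    """A modest survival forest fitted on the first 800 patients."""
    train = small_cohort.iloc[:800]
    model = fit_survival_forest(train, ForestConfig(20, 2, 40, seed=1))
    return model, train, small_cohort.iloc[800:].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
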