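import numpy as np
import pytest

from copsurv import synth
from copsurv.joint_fit import BivariateData


@pytest.fixture(scope="session")
def default_cohort():
    """One study-conditions cohort (n=315, rounded months, calibrated)."""
    df, truth = synth.generate_cohort(synth.CohortConfig(), seed=11)
    return df, truth


@pytest.fixture(scope="session")
def continuous_cohort():
    """Same conditions with continuous times (exact Clayton-Weibull data)."""
    cfg = synth.CohortConfig(rounding="none")
    df, truth = synth.generate_cohort(cfg, seed=11)
    return df, truth


@pytest.fixture(scope="session")
def continuous_data(continuous_cohort):
    return BivariateData.from_cohort(continuous_cohort[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
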