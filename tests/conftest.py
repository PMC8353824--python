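import numpy as np
import pytest

from timeusecox.pipeline import impute_cohort_zeros
from timeusecox.survival import CohortData, fit_compositional_cox, referent_composition
from timeusecox.synthetic import generate_cohort, whs_like_config


@pytest.fixture(scope="session")
def whs_cfg():
    """Calibrated generator configuration at a fit-friendly size."""
    return whs_like_config(n=2000, seed=11)


@pytest.fixture(scope="session")
def cohort(whs_cfg):
    """A zero-imputed analysis-ready synthetic cohort."""
    table, _ = generate_cohort(whs_cfg)
    table = impute_cohort_zeros(table)
    return CohortData(table=table, covariates=("age", "smoker"))


@pytest.fixture(scope="session")
def fitted(cohort):
    return fit_compositional_cox(cohort)


@pytest.fixture(scope="session")
def referent_minutes(cohort):
    return referent_composition(cohort, in_minutes=True)
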