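import numpy as np
import pytest

from cacsim.cohort import REFERENCE_COUNTS, assign_event_hazards, generate_cohort
from cacsim.parameters import LifeTable, build_parameter_set, load_life_table


@pytest.fixture(scope="session")
def ps():
    return build_parameter_set()


@pytest.fixture(scope="session")
def life_table():
    return load_life_table()


@pytest.fixture(scope="session")
def zero_mortality():
    return LifeTable.zero_mortality()


@pytest.fixture(scope="session")
def exact_cohort(ps):
    """The exact published 1,619-patient cohort with 5-year CVD hazards."""
    cohort = generate_cohort(REFERENCE_COUNTS.total, seed=1, exact=True)
    return assign_event_hazards(cohort, ps.event_rates("cvd", 5), "cvd", horizon=5)


def single_patient_cohort(age=60.0, risk=0.0, eligible=True, stratum=2):
    """One-patient cohort for closed-form checks."""
    import pandas as pd

    from cacsim.cohort import CohortTable

    records = pd.DataFrame(
        {
            "id": [0],
            "age": [age],
            "atp3_eligible": [eligible],
            "cac_stratum": [stratum],
            "annual_event_risk": [risk],
        }
    )
    return CohortTable(records, outcome_type="cvd", horizon=5)
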