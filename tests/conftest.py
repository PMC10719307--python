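import numpy as np
import pandas as pd
import pytest

from mallostasis import (
    FitConfig,
    LongitudinalCohort,
    fit,
    mallostatic_scenario,
    simulate_cohort,
    standardize,
)


@pytest.fixture(scope="session")
def scenario_bundle():
    """Canonical drifting-network cohort reused across the suite."""
    config = mallostatic_scenario(m=5, n=400, seed=1)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def std_bundle(scenario_bundle):
    cohort, scaling = standardize(scenario_bundle.cohort)
    return cohort, scaling


@pytest.fixture(scope="session")
def full_fit(std_bundle):
    cohort, _ = std_bundle
    return fit(cohort, FitConfig(model_form="full"))


@pytest.fixture()
def toy_cohort():
    """Three individuals, two biomarkers, death/censoring events."""
    data = pd.DataFrame(
        {
            "id": ["a", "a", "a", "b", "b", "c"],
            "age": [65.0, 68.0, 71.0, 66.0, 69.2, 70.0],
            "bm1": [1.0, 2.0, 3.0, 0.5, np.nan, 2.5],
            "bm2": [0.0, -1.0, 1.0, 2.0, 1.5, np.nan],
            "sex": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        }
    )
    events = pd.DataFrame(
        {"event_age": [73.0, 71.0, 75.0], "event_status": [1, 0, 1]},
        index=pd.Index(["a", "b", "c"], name="id"),
    )
    return LongitudinalCohort(data, ["bm1", "bm2"], ["sex"], events)
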