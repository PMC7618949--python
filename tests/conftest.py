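import numpy as np
import pytest

import restmeg as rm


@pytest.fixture(scope="session")
def fs() -> float:
    return 250.0


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort small enough for pipeline-level tests."""
    spec = rm.CohortSpec(
        n_subjects_per_group=4,
        groups=("HC", "AD"),
        n_parcels=6,
        duration=60.0,
        seed=7,
        age_range=(50.0, 80.0),
    )
    cohort = rm.generate_cohort(spec, rm.neurodegeneration_ground_truth(6))
    return spec, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
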