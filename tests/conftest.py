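import numpy as np
import pytest
from hypothesis import settings

import painmap

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> painmap.SyntheticCohort:
    """A 3-patient, 2-trial cohort for fast integration tests."""
    return painmap.generate_cohort(
        painmap.CohortConfig(n_patients=3, n_trials=2, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def reduced_settings(seed: int) -> painmap.MCMCSettings:
    """Short-chain settings for replicate-heavy simulation tests."""
    return painmap.MCMCSettings(
        n_iterations=1500, n_burn_in=500, n_chains=2, seed=seed
    )
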