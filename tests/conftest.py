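import numpy as np
import pytest

from gratio_dev import cohort as cohort_mod

#: The 18 study ages (days), ascending.
STUDY_AGES = [102, 116, 123, 124, 129, 354, 357, 362, 376, 663, 717,
              940, 1228, 1381, 1978, 2334, 2713, 2713]


@pytest.fixture(scope="session")
def default_laws():
    return cohort_mod.default_growth_laws()


@pytest.fixture(scope="session")
def small_cohort(default_laws):
    """Default 18-subject cohort on a small 16^3 grid, fixed seed."""
    spec = cohort_mod.CohortSpec(subjects=cohort_mod.default_cohort_ages(),
                                 growth_laws=default_laws,
                                 grid_shape=(16, 16, 16), rng_seed=42)
    return cohort_mod.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
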