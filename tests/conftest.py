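import numpy as np
import pytest
from hypothesis import settings

import gdmsim as g

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_small():
    """4,000-pregnancy cohort, no ascertainment dip."""
    return g.generate_cohort(g.CohortSpec(n_patients=4000, seed=7))


@pytest.fixture(scope="session")
def frame_small(cohort_small):
    """EHR-style labels at the measured discordance (FNR 14.3%, FPR 2.3%)."""
    return g.corrupt_cohort(cohort_small, g.NoiseSpec(seed=7))


@pytest.fixture(scope="session")
def cohort_mid_dip():
    """20,000-pregnancy cohort with the 2020 under-ascertainment preset."""
    return g.generate_cohort(
        g.CohortSpec(n_patients=20000, seed=13).with_2020_dip()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
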