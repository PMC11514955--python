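import numpy as np
import pytest

from imgene.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: enough structure for every stage, runs in seconds."""
    return SimConfig(n_patients=60, n_pn_positive=15, n_mihc_patients=12,
                     rois_per_patient=(2, 3), cells_per_roi=80.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def full_cohort():
    """One default-scale cohort shared by the slower recovery checks."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
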