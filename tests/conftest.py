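import numpy as np
import pytest

from emdad import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects/class, 4 trials, 3 channels — fast but CV-feasible."""
    spec = CohortSpec(subjects_per_class=3, trials_per_subject=4,
                      n_channels=3, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(subjects_per_class=3, trials_per_subject=4,
                      n_channels=3, seed=7)
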