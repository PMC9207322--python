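import numpy as np
import pytest

from ergdwt.simulate import CohortSpec, EpochSpec, ERGModelParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def epoch():
    return EpochSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by I/O and pipeline tests."""
    spec = CohortSpec(
        group_sizes={"ASD": 4, "ADHD": 3, "control": 5},
        seed=7,
        base_params=ERGModelParams(noise_sd=1.0),
    )
    return generate_cohort(spec)
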