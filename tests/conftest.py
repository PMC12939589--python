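import numpy as np
import pytest

from radsurv import SyntheticSpec, generate_cohort

#: seven small blocks summing to 20 features for fast protocol tests
TINY_BLOCKS = {
    "FirstOrder": 3, "Shape": 3, "GLCM": 3, "GLSZM": 3,
    "GLRLM": 3, "NGTDM": 3, "GLDM": 2,
}


def tiny_spec(n_patients=60, seed=0, **kw):
    defaults = dict(
        n_patients=n_patients,
        block_sizes=dict(TINY_BLOCKS),
        planted_effects={"NGTDM_00": 0.8},
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients x 20 features with one planted NGTDM effect."""
    return generate_cohort(tiny_spec(seed=101))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort: 398 patients x 107 features."""
    return generate_cohort(SyntheticSpec(seed=2024))


@pytest.fixture
def toy_survival():
    """Mixed censored toy set {(1,1),(2,0),(3,1),(3,1),(4,0)}."""
    time = np.array([1.0, 2.0, 3.0, 3.0, 4.0])
    event = np.array([1, 0, 1, 1, 0])
    return time, event
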