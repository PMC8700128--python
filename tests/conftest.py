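import numpy as np
import pytest

import connbench as cb

BASE_SEED = 1000


@pytest.fixture(scope="session")
def s1_panels():
    """100 realizations of system S1 at the benchmark sample size."""
    return [cb.simulate("S1", 2000, seed=BASE_SEED + r) for r in range(100)]


@pytest.fixture(scope="session")
def s2_panels():
    """100 realizations of system S2 at the benchmark sample size."""
    return [cb.simulate("S2", 2000, seed=BASE_SEED + r) for r in range(100)]


@pytest.fixture(scope="session")
def s3_panels_20():
    """20 realizations of system S3 for the scaled qualitative checks."""
    return [cb.simulate("S3", 2000, seed=BASE_SEED + r) for r in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
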