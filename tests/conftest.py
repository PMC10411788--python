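import numpy as np
import pytest

from egmo.baselines import get_baseline
from egmo.datasets import make_synthetic
from egmo.frequentist import StressStrengthData


@pytest.fixture(scope="session")
def small_data():
    """Tiny fixed stress-strength pair for score/likelihood checks."""
    rng = np.random.default_rng(1)
    return StressStrengthData(rng.gamma(2.0, 1.0, 5), rng.gamma(2.0, 1.0, 5))


@pytest.fixture(scope="session")
def weibull_baseline():
    return get_baseline("weibull", [1.3, 0.9])


@pytest.fixture(scope="session")
def exp_baseline():
    return get_baseline("exponential", [0.8])


@pytest.fixture(scope="session")
def synthetic_exp_pair():
    """Moderate synthetic EGMO-E pair at the baseline-collapse truth."""
    return make_synthetic(1.0, 1.0, 1.0, 1.0, "exponential", [1.0],
                          1000, 1000, seed=3)
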