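import numpy as np
import pytest
from hypothesis import settings

import swaylab as sl

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def small_sway_params():
    """Short trials (6 s at 100 Hz) keep estimator tests fast while staying
    well above every estimator's minimum length."""
    return sl.SwayGeneratorParams(duration=6.0)


@pytest.fixture(scope="session")
def small_cohort(small_sway_params):
    """4 + 4 subjects, two conditions, CoP and IMU trials."""
    return sl.gen_cohort(
        4, 4, sway=small_sway_params, master_seed=11, conditions=("2eo", "ecR")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def logistic_map(n: int, x0: float = 0.4) -> np.ndarray:
    """Fully chaotic logistic map x_{t+1} = 4 x_t (1 - x_t)."""
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x
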