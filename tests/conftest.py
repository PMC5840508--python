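import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wavinfo as wi

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_small():
    """Reduced benchmark dataset: 4 classes x 20 trials, 128 samples."""
    return wi.simulate_dataset(wi.SimulationConfig(trials_per_class=20, seed=7))


@pytest.fixture(scope="session")
def cfg_small():
    """Lighter selection settings for unit tests of the pipeline plumbing."""
    return wi.WIConfig(n_subaverages=50, trials_per_average=15, seed=7)


def haar_basis(n: int, n_levels: int) -> np.ndarray:
    """Explicit orthonormal Haar basis, rows ordered [A_L | D_L | ... | D_1].

    Independent construction used as the oracle for the fast transform:
    approximation rows are constant 2^{-L/2} on blocks of 2^L samples; detail
    rows at level j are +2^{-j/2} on the first half of a 2^j block and
    -2^{-j/2} on the second half.
    """
    rows = []
    block = 1 << n_levels
    for k in range(n // block):
        v = np.zeros(n)
        v[k * block:(k + 1) * block] = 2.0 ** (-n_levels / 2)
        rows.append(v)
    for j in range(n_levels, 0, -1):
        step = 1 << j
        for k in range(n // step):
            v = np.zeros(n)
            v[k * step:k * step + step // 2] = 2.0 ** (-j / 2)
            v[k * step + step // 2:(k + 1) * step] = -(2.0 ** (-j / 2))
            rows.append(v)
    return np.array(rows)
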