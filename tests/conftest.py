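import numpy as np
import pytest

from pmidelim import GeneratorConfig, default_panel, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort40():
    """Default 40-case synthetic cohort, seed 1."""
    return generate_cohort(GeneratorConfig(n_cases=40, seed=1))


def random_profile_pairs(rng: np.random.Generator, grid: float = 0.01):
    """Random piecewise profile with durations on a 0.01 h grid (so a
    Riemann-sum oracle with that step is exact)."""
    n_seg = int(rng.integers(1, 6))
    durations = np.round(rng.uniform(0.5, 40.0, n_seg) / grid) * grid
    temps = rng.uniform(-10.0, 25.0, n_seg)
    return list(zip(durations, temps))
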