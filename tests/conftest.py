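import numpy as np
import pytest

from rdnacn import simulate


@pytest.fixture(scope="session")
def default_looped():
    return simulate.default_looped()


@pytest.fixture(scope="session")
def toy_reference():
    """(unit, annotation, genome-with-planted-pseudocopy, mask)."""
    return simulate.simulate_reference_fixture(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-sample simulated cohort shared across unit tests."""
    cfg = simulate.SimulationConfig(n_samples=12, n_exome_bases=5000)
    return simulate.simulate_cohort(cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
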