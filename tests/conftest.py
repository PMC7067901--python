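import pytest

from famprio.fixtures import build_paper_fixtures
from famprio.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle():
    """Worked-example fixture bundle reconstructed from printed tables."""
    return build_paper_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=20240, n_background_variants=150))
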