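import pytest

from telecosim.costs import CostInputs
from telecosim.population import PopulationParams, generate_population


@pytest.fixture(scope="session")
def small_population():
    """Moderate synthetic cohort shared across tests (seeded, immutable)."""
    return generate_population(PopulationParams(n_patients=4000, seed=3))


@pytest.fixture()
def cost_inputs():
    return CostInputs()
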