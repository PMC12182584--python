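import pytest

from wdds import core_registry, table4_fixture
from wdds.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def registry():
    return core_registry()


@pytest.fixture()
def fixture_dataset():
    """The packaged worked example (two swabs, one vampire bat)."""
    return table4_fixture()


@pytest.fixture(scope="session")
def simple_dataset():
    """A small conformant synthetic dataset, one test per animal."""
    return generate(SyntheticConfig(n_animals=50, design="simple",
                                    prevalence=0.5, seed=101))
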