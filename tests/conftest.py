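import pytest

from rbh3kit.align_phylo import get_blosum62
from rbh3kit.synthetic_data import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def blosum():
    return get_blosum62()


@pytest.fixture(scope="session")
def default_family():
    """One synthetic 24-taxon family under the packaged default plan."""
    return simulate_family(SimulationConfig(seed=1))
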