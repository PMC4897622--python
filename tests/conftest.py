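import numpy as np
import pytest

from cartwheel.geometry import assemble_ideal_ring, build_homodimer
from cartwheel.species import build_species_tables


@pytest.fixture(scope="session")
def model():
    return build_homodimer()


@pytest.fixture(scope="session")
def ring():
    return assemble_ideal_ring(9)


@pytest.fixture(scope="session")
def species_tables():
    return build_species_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
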