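import numpy as np
import pytest

from presep import load_property_table
from presep.aa_properties import AMINO_ACIDS

from naive_pseaac import load_raw_scales


@pytest.fixture(scope="session")
def table():
    return load_property_table()


@pytest.fixture(scope="session")
def raw_scales():
    return load_raw_scales()


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
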