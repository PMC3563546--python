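import numpy as np
import pytest

from mdvflux.isotopes import ElementIsotopeTable, default_isotope_table
from mdvflux.model import FragmentDefinition


@pytest.fixture(scope="session")
def table():
    return default_isotope_table()


@pytest.fixture(scope="session")
def no_heavy_table():
    """A synthetic world without heavy isotopes: every correction is identity."""
    return ElementIsotopeTable(
        {el: (1.0,) for el in ("C", "H", "N", "O", "S", "Si", "X")}
    )


@pytest.fixture
def c2_fragment():
    """Bare two-carbon skeleton (no derivatization)."""
    return FragmentDefinition("frag", "C2", {"C": 2}, num_c=2, base_mass=100)


@pytest.fixture
def c3_fragment():
    """Three-carbon backbone, e.g. underivatized alanine molecular ion."""
    return FragmentDefinition("Ala", "Ala_C3", {"C": 3, "H": 7, "N": 1, "O": 2},
                              num_c=3, base_mass=89)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
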