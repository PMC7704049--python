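import numpy as np
import pytest

from foldrate.contacts import ContactParams, decompose_structure
from foldrate.synthetic import (
    ToyLandscape,
    linear_unfolding_network,
    make_hairpin_structure,
)


@pytest.fixture(scope="session")
def two_hairpin():
    """A two-hairpin toy structure with its substructure decomposition."""
    structure = make_hairpin_structure([6, 5])
    params = ContactParams(d_c=6.5, min_sep=3, c=7, h=5, f=1.7)
    decomp = decompose_structure(structure, params)
    return structure, params, decomp


@pytest.fixture(scope="session")
def small_landscape():
    """6-bit enumerable landscape: two cooperative 3-bit substructures."""
    return ToyLandscape(
        bit_energies=(-1.0,) * 6,
        bit_natives=(1, 1, 1, 1, 1, 1),
        groups=((0, 1, 2), (3, 4, 5)),
        group_bonus=(-2.0, -2.5),
    )


@pytest.fixture(scope="session")
def two_level_landscape():
    """Single-bit system with energy gap 1.5 (closed-form occupancy)."""
    return ToyLandscape(
        bit_energies=(-1.5,), bit_natives=(1,), groups=((0,),)
    )


@pytest.fixture(scope="session")
def linear_network():
    """4-substructure linear folding network with default Arrhenius truth."""
    return linear_unfolding_network()
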