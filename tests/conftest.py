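import numpy as np
import pytest

from htsumd.synth import (ToyReceptorSpec, make_planted_library,
                          make_toy_receptor)
from htsumd.systems import Fragment, Receptor, make_atom_set


@pytest.fixture(scope="session")
def toy_receptor_site():
    return make_toy_receptor(ToyReceptorSpec())


@pytest.fixture(scope="session")
def toy_receptor(toy_receptor_site):
    return toy_receptor_site[0]


@pytest.fixture(scope="session")
def toy_site(toy_receptor_site):
    return toy_receptor_site[1]


@pytest.fixture(scope="session")
def planted_library():
    return make_planted_library(40, 0.125, seed=1)


@pytest.fixture(scope="session")
def binder_fragment(planted_library):
    return planted_library.fragments[0]


def simple_receptor(coords, elements, charges=None, res_numbers=None):
    return make_atom_set(elements, np.asarray(coords, dtype=float),
                         charges=charges, res_numbers=res_numbers,
                         cls=Receptor)


def simple_fragment(coords, elements, charges=None, bonds=None,
                    fragment_id="frag"):
    coords = np.asarray(coords, dtype=float)
    if bonds is None and len(coords) > 1:
        bonds = [(i - 1, i) for i in range(1, len(coords))]
    return make_atom_set(elements, coords, charges=charges, bonds=bonds,
                         cls=Fragment, fragment_id=fragment_id)


@pytest.fixture
def bead_receptor():
    """Three one-atom 'residues' on the x axis."""
    return simple_receptor([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0],
                            [8.0, 0.0, 0.0]],
                           ["C", "O", "C"], res_numbers=[1, 2, 3])
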