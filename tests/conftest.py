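"""Shared fixtures: toy structures, contact maps, and the contact potential."""

import numpy as np
import pytest

from tcsevo.pipeline import _chain_a_map, build_toy_contexts
from tcsevo.synthetic import make_toy_structure
from tcsevo.tables import mj_matrix


@pytest.fixture(scope="session")
def em():
    return mj_matrix()


@pytest.fixture(scope="session")
def toy_single():
    """Single-chain compact lattice fold, 20 residues."""
    return make_toy_structure(20, chains=1, seed=3)


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain toy complex, 30 residues per chain."""
    return make_toy_structure(30, chains=2, seed=0)


@pytest.fixture(scope="session")
def toy_contexts():
    """(toy, FS context, FBS context) at the standard desk scale."""
    return build_toy_contexts(n_res=30, seed=0, n_folding_decoys=100, n_binding_decoys=100)


@pytest.fixture(scope="session")
def chain_a_map(toy_complex):
    """Single-chain contact-map view of the complex's evolving chain."""
    return _chain_a_map(toy_complex, 30)
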