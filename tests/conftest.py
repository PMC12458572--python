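"""Shared fixtures: molecules, bases, and the expensive reference SCF runs.

Session-scoped fixtures cache the costly calculations (decane unscreened
reference, water screened/unscreened pair) so the consistency and
divide-and-conquer suites share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from lobehf.basis import basis_for_structure, default_basis
from lobehf.fixtures import make_chain, make_molecule
from lobehf.integrals import ScreeningConfig, build_screened_eris
from lobehf.scf import atomic_energies, scf_solve


@pytest.fixture(scope="session")
def basisdef():
    return default_basis()


@pytest.fixture(scope="session")
def h2():
    return make_molecule("H2")


@pytest.fixture(scope="session")
def h2o():
    return make_molecule("H2O")


@pytest.fixture(scope="session")
def ch4():
    return make_molecule("CH4")


@pytest.fixture(scope="session")
def decane():
    return make_chain("alkane", 10)


@pytest.fixture(scope="session")
def h2_scf(h2, basisdef):
    basis = basis_for_structure(h2, basisdef)
    eris = build_screened_eris(basis, ScreeningConfig.disabled())
    return scf_solve(h2, basis, eris=eris), basis, eris


@pytest.fixture(scope="session")
def h2o_scf_unscreened(h2o, basisdef):
    basis = basis_for_structure(h2o, basisdef)
    eris = build_screened_eris(basis, ScreeningConfig.disabled())
    return scf_solve(h2o, basis, eris=eris), basis, eris


@pytest.fixture(scope="session")
def h2o_scf_screened(h2o, basisdef):
    basis = basis_for_structure(h2o, basisdef)
    eris = build_screened_eris(basis, ScreeningConfig())
    return scf_solve(h2o, basis, eris=eris), basis, eris


@pytest.fixture(scope="session")
def decane_reference(decane, basisdef):
    """Unscreened decane: the in-house oracle for screening and D&C checks."""
    basis = basis_for_structure(decane, basisdef)
    eris = build_screened_eris(basis, ScreeningConfig.disabled())
    result = scf_solve(decane, basis, eris=eris)
    atomic = atomic_energies(result, basis)
    return result, basis, atomic


@pytest.fixture(scope="session")
def decane_screened(decane, basisdef):
    basis = basis_for_structure(decane, basisdef)
    eris = build_screened_eris(basis, ScreeningConfig())
    result = scf_solve(decane, basis, eris=eris)
    return result, basis, eris
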