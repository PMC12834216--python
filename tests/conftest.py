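import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crystalmct import (
    CrystalStructure,
    Lattice,
    MoleculeInstance,
    RigidMolecule,
)
from crystalmct.energy import PotentialModel
from crystalmct.fixtures import hex1, toy_potential


@pytest.fixture(scope="session")
def hexmol() -> RigidMolecule:
    return hex1()


@pytest.fixture(scope="session")
def potential() -> PotentialModel:
    return toy_potential()


@pytest.fixture(scope="session")
def single_atom() -> RigidMolecule:
    return RigidMolecule(("C",), np.zeros((1, 3)), np.zeros(1), ("C",))


@pytest.fixture(scope="session")
def hex_crystal(hexmol) -> CrystalStructure:
    """A modest-density one-molecule crystal of the hexagon (not minimised)."""
    lat = Lattice.from_parameters(7.2, 7.4, 3.6, 90, 95, 90)
    rot = Rotation.from_euler("xyz", [20.0, 10.0, 5.0], degrees=True)
    return CrystalStructure(
        lat, (MoleculeInstance.from_rotation(np.array([0.1, 0.2, 0.3]), rot),), hexmol
    )


def random_hex_structure(hexmol, rng, n_molecules=1, min_contact=1.8):
    """Clash-free random P1 hexagon crystal for property tests."""
    from crystalmct.search import SearchConfig, generate_random_structure
    from crystalmct.core.structure import build_sampling_cell

    cfg = SearchConfig(
        space_groups=("P1",),
        density_window=(0.8, 1.1),
        clash_distance=min_contact,
        seed=0,
    )
    s = generate_random_structure(hexmol, "P1", cfg, rng)
    if n_molecules > 1:
        s = build_sampling_cell(s, n_molecules)
    return s
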