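"""Core crystallographic types: lattices, Niggli reduction, CIF, symmetry."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crystalmct import (
    CrystalStructure,
    Lattice,
    MoleculeInstance,
    RigidMolecule,
    build_sampling_cell,
    expand_to_p1,
    niggli_reduce,
    niggli_reset,
    read_cif,
    write_cif,
)
from crystalmct.core import CifParseError, CompositionError, get_symmetry_ops
from crystalmct.core.structure import AVOGADRO
from crystalmct.energy import lattice_energy


def random_lattice(rng):
    while True:
        m = rng.uniform(-1, 1, (3, 3)) * 10 + np.eye(3) * 10
        if np.linalg.det(m) > 30:
            return Lattice(m)


class TestLattice:
    def test_fractional_cartesian_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            lat = random_lattice(rng)
            f = rng.random((5, 3))
            assert np.allclose(lat.to_fractional(lat.to_cartesian(f)), f, atol=1e-10)

    def test_rejects_left_handed_and_degenerate(self):
        with pytest.raises(ValueError):
            Lattice(-np.eye(3))
        with pytest.raises(ValueError):
            Lattice(np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0.0]]))

    def test_parameters_round_trip(self):
        lat = Lattice.from_parameters(7.1, 8.2, 9.3, 77.0, 88.0, 99.0)
        assert np.allclose(lat.parameters, (7.1, 8.2, 9.3, 77.0, 88.0, 99.0))

    def test_bad_angles_rejected(self):
        with pytest.raises(ValueError):
            Lattice.from_parameters(5, 5, 5, 0.0, 90, 90)
        with pytest.raises(ValueError):
            Lattice.from_parameters(5, 5, 5, 10.0, 170.0, 90.0)


class TestNiggli:
    def test_reduces_skewed_cell_and_conserves_volume(self):
        lat = Lattice.from_parameters(10, 10, 10, 90, 90, 150)
        red, P = niggli_reduce(lat)
        assert red.is_niggli()
        assert abs(red.volume - lat.volume) < 1e-8 * lat.volume
        assert abs(abs(np.linalg.det(P)) - 1) < 1e-12
        assert np.allclose(P.astype(float) @ lat.matrix, red.matrix)

    def test_idempotent(self):
        lat = Lattice.from_parameters(10, 10, 10, 90, 90, 150)
        red, _ = niggli_reduce(lat)
        red2, P2 = niggli_reduce(red)
        assert np.allclose(red2.matrix, red.matrix)
        assert np.allclose(P2, np.eye(3))

    def test_cubic_already_reduced(self):
        lat = Lattice(np.eye(3) * 10.0)
        red, P = niggli_reduce(lat)
        assert np.allclose(red.matrix, lat.matrix)
        assert np.allclose(P, np.eye(3))

    def test_random_lattices_satisfy_conditions(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lat = random_lattice(rng)
            red, _ = niggli_reduce(lat)
            assert red.is_niggli()
            assert abs(red.volume - lat.volume) < 1e-8 * lat.volume


class TestRigidMolecule:
    def test_centroid_enforced(self):
        with pytest.raises(ValueError):
            RigidMolecule(("C",), np.array([[1.0, 0, 0]]), np.zeros(1), ("C",))

    def test_from_coords_recentres(self):
        m = RigidMolecule.from_coords(
            ("C", "C"), np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.zeros(2), ("C", "C")
        )
        assert np.allclose(m.local_coords.mean(axis=0), 0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            RigidMolecule(("C", "H"), np.zeros((2, 3)), np.zeros(1), ("C", "H"))

    def test_invalid_element_rejected(self):
        with pytest.raises(ValueError):
            RigidMolecule(("Zz",), np.zeros((1, 3)), np.zeros(1), ("Zz",))

    def test_hexagon_is_planar_and_neutral(self, hexmol):
        assert hexmol.plane_rms() < 1e-6
        assert abs(hexmol.total_charge) < 1e-12


class TestCif:
    def test_round_trip(self, hex_crystal, tmp_path):
        path = tmp_path / "x.cif"
        write_cif(hex_crystal, path)
        back = read_cif(path, hex_crystal.molecule_ref)
        a = np.sort(hex_crystal.atom_coords_cart().reshape(-1, 3), axis=0)
        b = np.sort(back.atom_coords_cart().reshape(-1, 3), axis=0)
        assert np.abs(a - b).max() < 1e-6

    def test_atom_count(self, hex_crystal, tmp_path):
        cell4 = build_sampling_cell(hex_crystal, 4)
        path = tmp_path / "four.cif"
        write_cif(cell4, path)
        n_sites = sum(
            1 for line in path.read_text().splitlines()
            if line and line[0] in "CH" and not line.startswith("C2/")
        )
        assert n_sites == 4 * hex_crystal.molecule_ref.n_atoms

    def test_single_molecule_density(self, hexmol, tmp_path):
        lat = Lattice(np.eye(3) * 30.0)
        s = CrystalStructure(lat, (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),), hexmol)
        path = tmp_path / "one.cif"
        write_cif(s, path)
        back = read_cif(path, hexmol)
        assert back.n_molecules == 1
        expected = hexmol.mass / AVOGADRO / (27000 * 1e-24)
        assert abs(back.density - expected) < 1e-9

    def test_degenerate_cell_rejected(self, hexmol, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text(
            "data_bad\n_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "_cell_angle_alpha 0\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
            "loop_\n_atom_site_type_symbol\n_atom_site_fract_x\n"
            "_atom_site_fract_y\n_atom_site_fract_z\nC 0 0 0\n"
        )
        with pytest.raises(CifParseError):
            read_cif(path, hexmol)

    def test_wrong_composition_rejected(self, hexmol, single_atom, tmp_path):
        lat = Lattice(np.eye(3) * 20.0)
        s = CrystalStructure(lat, (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),), single_atom)
        path = tmp_path / "atom.cif"
        write_cif(s, path)
        with pytest.raises(CompositionError):
            read_cif(path, hexmol)

    def test_written_coordinates_are_wrapped(self, hexmol, tmp_path):
        lat = Lattice(np.eye(3) * 20.0)
        s = CrystalStructure(
            lat, (MoleculeInstance(np.array([1.25, 0.5, 0.5]), [0, 0, 0, 1]),), hexmol
        )
        # MoleculeInstance wraps on construction
        assert np.allclose(s.molecules[0].frac_position, [0.25, 0.5, 0.5])
        path = tmp_path / "w.cif"
        write_cif(s, path)
        for line in path.read_text().splitlines():
            parts = line.split()
            if len(parts) == 5 and parts[1] in ("C", "H"):
                assert all(0.0 <= float(v) < 1.0 for v in parts[2:])


class TestSymmetry:
    @pytest.mark.parametrize(
        "sg,order", [("P-1", 2), ("P21", 2), ("P21/c", 4), ("P212121", 4),
                     ("C2/c", 8), ("Pbca", 8)]
    )
    def test_group_orders(self, sg, order):
        assert len(get_symmetry_ops(sg)) == order

    def test_p1_expansion_is_identity(self, hex_crystal):
        assert expand_to_p1(hex_crystal) is hex_crystal

    def test_p212121_expansion_counts(self, hexmol):
        lat = Lattice.from_parameters(9, 10, 11, 90, 90, 90)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True)
        s = CrystalStructure(
            lat, (MoleculeInstance.from_rotation([0.1, 0.2, 0.3], rot),),
            hexmol, space_group="P212121",
        )
        p1 = expand_to_p1(s)
        assert p1.n_molecules == 4
        assert p1.space_group == "P1"

    def test_inversion_preserves_energy_per_molecule(self, hexmol, potential):
        lat = Lattice.from_parameters(8, 9, 7, 85, 95, 90)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True)
        s = CrystalStructure(
            lat, (MoleculeInstance.from_rotation([0.13, 0.22, 0.31], rot),),
            hexmol, space_group="P-1",
        )
        p1 = expand_to_p1(s)
        assert p1.n_molecules == 2
        # the P1 cell contains the asymmetric molecule + its image; energy per
        # molecule must equal that of the same crystal described any other way
        e2 = lattice_energy(p1, potential, clash_check=False).total_per_molecule
        e4 = lattice_energy(
            build_sampling_cell(p1, 4), potential, clash_check=False
        ).total_per_molecule
        assert abs(e2 - e4) < 1e-6

    def test_overlapping_copies_rejected(self, hexmol):
        lat = Lattice.from_parameters(8, 9, 7, 85, 95, 90)
        s = CrystalStructure(
            lat, (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),),
            hexmol, space_group="P-1",
        )  # molecule on the inversion centre duplicates onto itself
        with pytest.raises(ValueError):
            expand_to_p1(s)


class TestSamplingCell:
    def test_doubling_to_four(self, hex_crystal, potential):
        cell = build_sampling_cell(hex_crystal, 4)
        assert cell.n_molecules == 4
        assert abs(cell.density - hex_crystal.density) < 1e-12
        e1 = lattice_energy(hex_crystal, potential, clash_check=False).total_per_molecule
        e4 = lattice_energy(cell, potential, clash_check=False).total_per_molecule
        assert abs(e1 - e4) < 1e-6

    def test_identity_when_already_at_target(self, hex_crystal):
        cell = build_sampling_cell(hex_crystal, 4)
        assert build_sampling_cell(cell, 4) is cell

    def test_doubles_along_shortest_axis(self, hexmol):
        lat = Lattice(np.diag([5.0, 20.0, 20.0]))
        s = CrystalStructure(
            lat,
            (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),
             MoleculeInstance(np.array([0.5, 0.25, 0.25]), [0, 0, 0, 1])),
            hexmol,
        )
        cell = build_sampling_cell(s, 4)
        assert np.allclose(np.linalg.norm(cell.lattice.matrix, axis=1), [10, 20, 20])

    def test_unreachable_target_rejected(self, hexmol):
        lat = Lattice(np.eye(3) * 12.0)
        mols = tuple(
            MoleculeInstance(np.array(f), [0, 0, 0, 1])
            for f in ([0, 0, 0], [0.33, 0.33, 0.33], [0.66, 0.66, 0.66])
        )
        s = CrystalStructure(lat, mols, hexmol)
        with pytest.raises(ValueError, match="doubling"):
            build_sampling_cell(s, 4)

    def test_niggli_reset_preserves_crystal(self, hex_crystal, potential):
        # re-express the same crystal in a skewed (unimodular) basis
        P = np.array([[1, 0, 0], [3, 1, 0], [0, 0, 1.0]])
        skewed = CrystalStructure(
            Lattice(P @ hex_crystal.lattice.matrix),
            tuple(
                MoleculeInstance(m.frac_position @ np.linalg.inv(P), m.orientation)
                for m in hex_crystal.molecules
            ),
            hex_crystal.molecule_ref,
        )
        reset = niggli_reset(skewed)
        e0 = lattice_energy(reset, potential, clash_check=False).total_per_molecule
        e1 = lattice_energy(skewed, potential, clash_check=False).total_per_molecule
        assert abs(e0 - e1) < 1e-8
        assert abs(reset.density - skewed.density) < 1e-12
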