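"""Lattice energy, Ewald electrostatics, analytic gradients, minimisation."""
import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from crystalmct import (
    CrystalStructure,
    Lattice,
    MoleculeInstance,
    RigidMolecule,
    build_sampling_cell,
)
from crystalmct.energy import (
    COULOMB_CONSTANT,
    ClashError,
    ParameterError,
    PotentialModel,
    energy_gradient,
    ewald_energy,
    lattice_energy,
)
from crystalmct.minimize import minimize_structure, right_jacobian
from conftest import random_hex_structure


@pytest.fixture(scope="module")
def pair_potential():
    return PotentialModel({"C": (1e5, 3.0, 1e3)}, cutoff=15.0)


class TestPotentialModel:
    def test_combining_rules(self):
        pot = PotentialModel({"A": (100.0, 3.0, 10.0), "B": (400.0, 4.0, 40.0)})
        A, B, C = pot.pair("A", "B")
        assert A == pytest.approx(200.0)
        assert B == pytest.approx(3.5)
        assert C == pytest.approx(20.0)

    def test_explicit_pair_override(self):
        pot = PotentialModel(
            {"A": (100.0, 3.0, 10.0)}, pair_params={("A", "A"): (1.0, 2.0, 3.0)}
        )
        assert pot.pair("A", "A") == (1.0, 2.0, 3.0)

    def test_missing_pair_raises(self, hex_crystal):
        pot = PotentialModel({"C_ar": (369743.0, 3.6, 2439.8)})
        with pytest.raises(ParameterError):
            lattice_energy(hex_crystal, pot)

    def test_cutoff_floor(self):
        with pytest.raises(ValueError):
            PotentialModel({"C": (1.0, 1.0, 1.0)}, cutoff=5.0)

    def test_file_round_trip(self, potential, tmp_path):
        path = tmp_path / "pot.json"
        potential.to_file(path)
        back = PotentialModel.from_file(path)
        assert back.pair("C_ar", "H") == pytest.approx(potential.pair("C_ar", "H"))
        assert back.cutoff == potential.cutoff


class TestLatticeEnergy:
    def test_closed_form_pair(self, single_atom, pair_potential):
        """Two neutral atoms 4 A apart in a huge cell: hand-computed energy."""
        lat = Lattice(np.eye(3) * 50.0)
        s = CrystalStructure(
            lat,
            (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),
             MoleculeInstance(np.array([4 / 50, 0, 0]), [0, 0, 0, 1])),
            single_atom,
        )
        rep = lattice_energy(s, pair_potential)
        pair = 0.5 * (1e5 * math.exp(-12.0) - 1e3 / 4096.0)
        tail = -2 * math.pi * 4 * 1e3 / (3 * 50**3 * 15**3) / 2
        assert rep.total_per_molecule == pytest.approx(pair + tail, abs=1e-12)
        assert rep.electrostatic == 0.0

    def test_zero_charges_no_electrostatics(self, hexmol, potential, hex_crystal):
        neutral = RigidMolecule(
            hexmol.atom_elements, hexmol.local_coords,
            np.zeros(hexmol.n_atoms), hexmol.atom_types,
        )
        s = dataclasses.replace(hex_crystal, molecule_ref=neutral)
        rep = lattice_energy(s, potential, clash_check=False)
        assert rep.electrostatic == pytest.approx(0.0, abs=1e-12)

    def test_component_sum(self, hex_crystal, potential):
        rep = lattice_energy(hex_crystal, potential, clash_check=False)
        assert rep.total_per_molecule == pytest.approx(
            rep.repulsion_dispersion + rep.electrostatic, abs=1e-9
        )

    def test_clash_detected(self, single_atom, pair_potential):
        lat = Lattice(np.eye(3) * 20.0)
        s = CrystalStructure(
            lat,
            (MoleculeInstance(np.zeros(3), [0, 0, 0, 1]),
             MoleculeInstance(np.array([0.3 / 20, 0, 0]), [0, 0, 0, 1])),
            single_atom,
        )
        with pytest.raises(ClashError):
            lattice_energy(s, pair_potential)

    def test_supercell_invariance(self, hex_crystal, potential):
        e1 = lattice_energy(hex_crystal, potential, clash_check=False).total_per_molecule
        e4 = lattice_energy(
            build_sampling_cell(hex_crystal, 4), potential, clash_check=False
        ).total_per_molecule
        assert abs(e4 - e1) < 1e-6

    def test_molecule_reordering_invariance(self, hexmol, potential):
        rng = np.random.default_rng(5)
        s = random_hex_structure(hexmol, rng, n_molecules=4)
        perm = [2, 0, 3, 1]
        s2 = dataclasses.replace(s, molecules=tuple(s.molecules[i] for i in perm))
        e1 = lattice_energy(s, potential, clash_check=False).total_per_molecule
        e2 = lattice_energy(s2, potential, clash_check=False).total_per_molecule
        assert abs(e1 - e2) < 1e-8 * max(1.0, abs(e1))

    def test_unimodular_resetting_invariance(self, hexmol, potential):
        rng = np.random.default_rng(6)
        s = random_hex_structure(hexmol, rng)
        P = np.array([[1, 1, 0], [0, 1, 0], [1, 0, 1.0]])
        s2 = CrystalStructure(
            Lattice(P @ s.lattice.matrix),
            tuple(
                MoleculeInstance(m.frac_position @ np.linalg.inv(P), m.orientation)
                for m in s.molecules
            ),
            hexmol,
        )
        e1 = lattice_energy(s, potential, clash_check=False).total_per_molecule
        e2 = lattice_energy(s2, potential, clash_check=False).total_per_molecule
        assert abs(e1 - e2) < 1e-8 * max(1.0, abs(e1))

    def test_rigid_translation_invariance(self, hexmol, potential):
        rng = np.random.default_rng(7)
        s = random_hex_structure(hexmol, rng, n_molecules=2)
        shift = rng.random(3)
        s2 = dataclasses.replace(
            s,
            molecules=tuple(
                MoleculeInstance(m.frac_position + shift, m.orientation)
                for m in s.molecules
            ),
        )
        e1 = lattice_energy(s, potential, clash_check=False).total_per_molecule
        e2 = lattice_energy(s2, potential, clash_check=False).total_per_molecule
        assert abs(e1 - e2) < 1e-8 * max(1.0, abs(e1))


class TestEwald:
    def test_rock_salt_madelung_constant(self):
        a = 5.64
        lat = Lattice(np.eye(3) * a)
        base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        frac = np.vstack([base, base + [0.5, 0, 0]])
        charges = np.array([1.0] * 4 + [-1.0] * 4)
        E = ewald_energy(lat, frac @ lat.matrix, charges, accuracy=1e-8, cutoff=12.0)
        madelung = -E / 4 * (a / 2) / COULOMB_CONSTANT
        assert madelung == pytest.approx(1.747565, rel=1e-4)

    def test_accuracy_parameter_consistency(self):
        """Different accuracy/cutoff splits agree on the same charge sum."""
        lat = Lattice(np.eye(3) * 6.0)
        rng = np.random.default_rng(0)
        pos = rng.random((6, 3)) @ lat.matrix
        q = np.array([1, -1, 0.5, -0.5, 0.25, -0.25])
        e1 = ewald_energy(lat, pos, q, accuracy=1e-6, cutoff=9.0)
        e2 = ewald_energy(lat, pos, q, accuracy=1e-8, cutoff=14.0)
        assert e1 == pytest.approx(e2, rel=1e-5)


class TestGradient:
    @staticmethod
    def fd_gradient(s, potential, h=1e-5):
        def E(st):
            return lattice_energy(st, potential, clash_check=False).total_per_molecule

        g_frac = np.zeros((s.n_molecules, 3))
        g_rot = np.zeros((s.n_molecules, 3))
        for m_i in range(s.n_molecules):
            for c in range(3):
                def frac_shift(sign):
                    mols = list(s.molecules)
                    f = mols[m_i].frac_position.copy()
                    f[c] += sign * h
                    mols[m_i] = MoleculeInstance(f, mols[m_i].orientation)
                    return dataclasses.replace(s, molecules=tuple(mols))

                g_frac[m_i, c] = (E(frac_shift(1)) - E(frac_shift(-1))) / (2 * h)

                def rot_shift(sign):
                    mols = list(s.molecules)
                    th = np.zeros(3)
                    th[c] = sign * h
                    R = Rotation.from_quat(mols[m_i].orientation).as_matrix() @ \
                        Rotation.from_rotvec(th).as_matrix()
                    mols[m_i] = MoleculeInstance.from_rotation(
                        mols[m_i].frac_position, Rotation.from_matrix(R)
                    )
                    return dataclasses.replace(s, molecules=tuple(mols))

                g_rot[m_i, c] = (E(rot_shift(1)) - E(rot_shift(-1))) / (2 * h)
        g_cell = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Hp = s.lattice.matrix.copy()
                Hp[i, j] += h
                Hm = s.lattice.matrix.copy()
                Hm[i, j] -= h
                g_cell[i, j] = (
                    E(dataclasses.replace(s, lattice=Lattice(Hp)))
                    - E(dataclasses.replace(s, lattice=Lattice(Hm)))
                ) / (2 * h)
        return g_frac, g_rot, g_cell

    def test_matches_finite_differences(self, hexmol, potential):
        rng = np.random.default_rng(11)
        for _ in range(3):
            s = random_hex_structure(hexmol, rng, n_molecules=2)
            _, g = energy_gradient(s, potential)
            g_frac, g_rot, g_cell = self.fd_gradient(s, potential)
            scale = max(1.0, g.norm)
            assert np.abs(g.frac_positions - g_frac).max() < 1e-5 * scale
            assert np.abs(g.orientations - g_rot).max() < 1e-5 * scale
            assert np.abs(g.cell - g_cell).max() < 1e-5 * scale

    def test_translation_gradient_vanishes_for_isolated_molecule(self, hexmol, potential):
        lat = Lattice(np.eye(3) * 40.0)
        s = CrystalStructure(
            lat,
            (MoleculeInstance.from_rotation(
                [0.5, 0.5, 0.5], Rotation.from_euler("x", 30, degrees=True)
            ),),
            hexmol,
        )
        _, g = energy_gradient(s, potential)
        # no neighbours within the cutoff: translational force is zero
        assert np.abs(g.frac_positions).max() < 1e-10

    def test_stationary_at_minimum(self, hexmol, potential):
        from crystalmct.fixtures import make_two_basin_crystal_fixture

        _, pot, (ref, _) = make_two_basin_crystal_fixture()
        _, g = energy_gradient(ref, pot, soft_core=True)
        assert g.norm < 1e-4

    def test_right_jacobian_identity_at_zero(self):
        assert np.allclose(right_jacobian(np.zeros(3)), np.eye(3))


class TestMinimize:
    def test_dimer_reaches_pair_minimum(self, single_atom, pair_potential):
        r_star = minimize_scalar(
            lambda r: 1e5 * np.exp(-3 * r) - 1e3 * r**-6, bounds=(2, 8),
            method="bounded",
        ).x
        lat = Lattice(np.eye(3) * 40.0)
        s = CrystalStructure(
            lat,
            (MoleculeInstance(np.array([0.45, 0.5, 0.5]), [0, 0, 0, 1]),
             MoleculeInstance(np.array([0.55, 0.5, 0.5]), [0, 0, 0, 1])),
            single_atom,
        )
        m = minimize_structure(s, pair_potential, tol=1e-6, fix_lattice=True)
        df = m.molecules[1].frac_position - m.molecules[0].frac_position
        df -= np.round(df)
        sep = np.linalg.norm(df @ m.lattice.matrix)
        assert sep == pytest.approx(r_star, abs=1e-4)

    def test_minimum_is_fixed_point(self):
        from crystalmct.fixtures import make_two_basin_crystal_fixture

        _, pot, (ref, _) = make_two_basin_crystal_fixture()
        again = minimize_structure(ref, pot, tol=1e-4)
        assert again.energy == pytest.approx(ref.energy, abs=1e-6)

    def test_energy_never_increases(self, hexmol, potential):
        rng = np.random.default_rng(21)
        s = random_hex_structure(hexmol, rng)
        e0 = lattice_energy(s, potential, soft_core=True, clash_check=False).total_per_molecule
        m = minimize_structure(s, potential, tol=1e-4)
        assert m.energy <= e0 + 1e-10

    def test_symmetric_minimisation_preserves_group(self, hexmol, potential):
        lat = Lattice.from_parameters(8, 9, 7, 90, 100, 90)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True)
        s = CrystalStructure(
            lat, (MoleculeInstance.from_rotation([0.13, 0.22, 0.31], rot),),
            hexmol, space_group="P21/c",
        )
        m = minimize_structure(s, potential, tol=1e-3, fix_symmetry=True)
        assert m.space_group == "P21/c"
        a, b, c, al, be, ga = m.lattice.parameters
        assert al == pytest.approx(90.0, abs=1e-9)
        assert ga == pytest.approx(90.0, abs=1e-9)

    def test_recovery_rate_from_perturbations(self, potential):
        """Perturbed copies of a known minimum fall back into its basin."""
        from crystalmct.fingerprints import pattern_similarity, simulate_pxrd
        from crystalmct.fixtures import make_two_basin_crystal_fixture
        from crystalmct.threshold import MoveParams, propose_move

        _, pot, (ref, _) = make_two_basin_crystal_fixture()
        p_ref = simulate_pxrd(ref)
        rng = np.random.default_rng(0)
        params = MoveParams(max_translation=0.15, max_rotation=8.0, max_strain=0.015)
        hits = 0
        n = 40
        for _ in range(n):
            s = ref
            for _ in range(3):
                s = propose_move(s, params, rng)
            m = minimize_structure(s, pot, tol=1e-3, maxiter=200, rounds=2)
            if pattern_similarity(simulate_pxrd(m), p_ref) >= 0.98:
                hits += 1
        assert hits / n >= 0.95
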