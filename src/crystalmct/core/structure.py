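"""Crystal structures built from rigid molecules.

A :class:`CrystalStructure` is a lattice plus an ordered list of rigid-body
placements (fractional centroid + orientation quaternion) of a single
reference molecule.  Symmetry is represented explicitly: a structure either
carries a space-group label with its asymmetric unit, or is fully expanded
to P1 (the representation all Monte Carlo sampling works in).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .lattice import Lattice, niggli_reduce
from .molecule import RigidMolecule

__all__ = [
    "MoleculeInstance",
    "CrystalStructure",
    "expand_to_p1",
    "build_sampling_cell",
    "proper_orientation",
    "niggli_reset",
]

AVOGADRO = 6.02214076e23
_OVERLAP_TOL = 0.1  # A, symmetry-generated duplicates closer than this are an error


@dataclass(frozen=True)
class MoleculeInstance:
    """Placement of the reference molecule: fractional centroid + orientation.

    The orientation quaternion (x, y, z, w scalar-last, unit norm) rotates
    body-frame vectors into the crystal Cartesian frame.
    """

    frac_position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.frac_position, dtype=float) % 1.0
        q = np.asarray(self.orientation, dtype=float)
        if pos.shape != (3,) or q.shape != (4,):
            raise ValueError("frac_position must be length 3, orientation length 4")
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"orientation quaternion norm {norm} != 1")
        object.__setattr__(self, "frac_position", pos)
        object.__setattr__(self, "orientation", q / norm)

    @classmethod
    def from_rotation(cls, frac_position, rotation: Rotation) -> "MoleculeInstance":
        return cls(np.asarray(frac_position, dtype=float), rotation.as_quat())

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Column-convention rotation matrix R: x_crystal = R @ x_body."""
        return Rotation.from_quat(self.orientation).as_matrix()


@dataclass(frozen=True)
class CrystalStructure:
    lattice: Lattice
    molecules: tuple[MoleculeInstance, ...]
    molecule_ref: RigidMolecule
    space_group: str = "P1"
    z_prime: int = 1
    energy: float | None = None  # lattice energy per molecule, kJ/mol
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))
        if not self.molecules:
            raise ValueError("structure must contain at least one molecule")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_atoms(self) -> int:
        return self.n_molecules * self.molecule_ref.n_atoms

    @property
    def density(self) -> float:
        """Mass density in g/cm^3."""
        mass_g = self.n_molecules * self.molecule_ref.mass / AVOGADRO
        return mass_g / (self.lattice.volume * 1e-24)

    def centroids_cart(self) -> np.ndarray:
        frac = np.array([m.frac_position for m in self.molecules])
        return self.lattice.to_cartesian(frac)

    def atom_coords_cart(self) -> np.ndarray:
        """(n_molecules, n_atoms, 3) Cartesian atom coordinates."""
        local = self.molecule_ref.local_coords
        out = np.empty((self.n_molecules, local.shape[0], 3))
        centroids = self.centroids_cart()
        for i, mol in enumerate(self.molecules):
            out[i] = centroids[i] + local @ mol.rotation_matrix.T
        return out

    def with_energy(self, energy: float, converged: bool = True) -> "CrystalStructure":
        return replace(self, energy=energy, converged=converged)

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "lattice": self.lattice.matrix.tolist(),
            "molecules": [
                {"frac_position": m.frac_position.tolist(),
                 "orientation": m.orientation.tolist()}
                for m in self.molecules
            ],
            "molecule_ref": {
                "atom_elements": list(self.molecule_ref.atom_elements),
                "local_coords": self.molecule_ref.local_coords.tolist(),
                "charges": self.molecule_ref.charges.tolist(),
                "atom_types": list(self.molecule_ref.atom_types),
            },
            "space_group": self.space_group,
            "z_prime": self.z_prime,
            "energy": self.energy,
            "converged": self.converged,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrystalStructure":
        mol = RigidMolecule(
            tuple(d["molecule_ref"]["atom_elements"]),
            np.array(d["molecule_ref"]["local_coords"]),
            np.array(d["molecule_ref"]["charges"]),
            tuple(d["molecule_ref"]["atom_types"]),
        )
        return cls(
            lattice=Lattice(np.array(d["lattice"])),
            molecules=tuple(
                MoleculeInstance(np.array(m["frac_position"]), np.array(m["orientation"]))
                for m in d["molecules"]
            ),
            molecule_ref=mol,
            space_group=d.get("space_group", "P1"),
            z_prime=d.get("z_prime", 1),
            energy=d.get("energy"),
            converged=d.get("converged", True),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "CrystalStructure":
        return cls.from_dict(json.loads(Path(path).read_text()))


def proper_orientation(molecule: RigidMolecule, matrix: np.ndarray) -> np.ndarray:
    """Reduce a (possibly improper) orthogonal body->crystal map to a proper rotation.

    Symmetry operators with determinant -1 (inversions, glides, mirrors) can
    only place a rigid molecule if the molecule itself has an improper
    self-symmetry.  Planar molecules always do (reflection through the
    molecular plane); centrosymmetric molecules map onto themselves under
    body inversion.  Returns a proper rotation matrix producing the same
    atom positions, or raises ValueError.
    """
    det = np.linalg.det(matrix)
    if det > 0:
        return matrix
    coords = molecule.local_coords
    # candidate improper self-maps of the body frame
    n = molecule.plane_normal()
    candidates = [np.eye(3) - 2.0 * np.outer(n, n), -np.eye(3)]
    for s in candidates:
        mapped = coords @ s.T
        # each mapped atom must coincide with an atom of identical identity
        ok = True
        for i, p in enumerate(mapped):
            d = np.linalg.norm(coords - p, axis=1)
            j = int(np.argmin(d))
            if d[j] > 1e-6 or molecule.atom_types[j] != molecule.atom_types[i] \
               or abs(molecule.charges[j] - molecule.charges[i]) > 1e-9:
                ok = False
                break
        if ok:
            return matrix @ s
    raise ValueError(
        "improper symmetry operator applied to a molecule with no improper "
        "self-symmetry (not planar, not centrosymmetric)"
    )


def expand_to_p1(
    structure: CrystalStructure,
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CrystalStructure:
    """Expand a symmetric structure to P1 by applying the space-group operators.

    ``symmetry_ops`` are fractional-coordinate operators ``f' = f @ rot.T + tran``;
    if omitted they are looked up from the structure's space-group symbol.
    The output lists ``z_prime * |group|`` molecules and its per-molecule
    lattice energy is unchanged (the operators are isometries of the cell).
    """
    if structure.space_group == "P1" and symmetry_ops is None:
        return structure
    if symmetry_ops is None:
        from .spacegroups import get_symmetry_ops

        symmetry_ops = get_symmetry_ops(structure.space_group)
    H = structure.lattice.matrix
    Hinv = np.linalg.inv(H)
    new_molecules: list[MoleculeInstance] = []
    for mol in structure.molecules:
        for rot, tran in symmetry_ops:
            f_new = (mol.frac_position @ rot.T + tran) % 1.0
            A = Hinv @ rot.T @ H  # row-convention Cartesian map x' = x @ A
            M = A.T @ mol.rotation_matrix  # column-convention orientation
            # symmetry ops must be isometries of this cell
            if not np.allclose(M @ M.T, np.eye(3), atol=1e-6):
                raise ValueError(
                    "symmetry operator is not an isometry of the given lattice; "
                    "cell parameters are incompatible with the space group"
                )
            R = proper_orientation(structure.molecule_ref, M)
            new_molecules.append(
                MoleculeInstance.from_rotation(f_new, Rotation.from_matrix(R))
            )
    # reject overlapping duplicates (minimum-image centroid distance)
    frac = np.array([m.frac_position for m in new_molecules])
    for i in range(len(frac)):
        d = frac[i + 1:] - frac[i]
        d -= np.round(d)
        if len(d) and np.linalg.norm(d @ H, axis=1).min() < _OVERLAP_TOL:
            raise ValueError(
                "symmetry expansion generated overlapping molecules "
                f"(centroid distance < {_OVERLAP_TOL} A); special position not supported"
            )
    return CrystalStructure(
        lattice=structure.lattice,
        molecules=tuple(new_molecules),
        molecule_ref=structure.molecule_ref,
        space_group="P1",
        z_prime=len(new_molecules),
        energy=structure.energy,
    )


def build_sampling_cell(structure: CrystalStructure, target_molecules: int = 4) -> CrystalStructure:
    """Grow a P1 cell to the sampling size by doubling along the shortest axis.

    Each doubling duplicates the cell contents along the currently shortest
    cell vector, so the per-molecule energy and density are invariant.  The
    target must be the current molecule count times a power of two;
    otherwise a ValueError instructs the caller to sample in the original
    cell (cells that already hold the target -- or e.g. eight molecules --
    are used as they are, with more sampling).
    """
    if structure.space_group != "P1":
        raise ValueError("sampling cells are built from P1 structures; expand first")
    n = structure.n_molecules
    if target_molecules == n:
        return structure
    ratio = target_molecules / n
    k = np.log2(ratio) if ratio > 0 else -1
    if ratio < 1 or abs(k - round(k)) > 1e-12:
        raise ValueError(
            f"cannot reach {target_molecules} molecules from {n} by cell doubling; "
            "keep the original cell and scale the sampling instead"
        )
    out = structure
    for _ in range(int(round(k))):
        axis = int(np.argmin(np.linalg.norm(out.lattice.matrix, axis=1)))
        new_matrix = out.lattice.matrix.copy()
        new_matrix[axis] *= 2.0
        mols = []
        for shift in (0.0, 0.5):
            for m in out.molecules:
                f = m.frac_position.copy()
                f[axis] = f[axis] / 2.0 + shift
                mols.append(MoleculeInstance(f, m.orientation))
        out = CrystalStructure(
            lattice=Lattice(new_matrix),
            molecules=tuple(mols),
            molecule_ref=out.molecule_ref,
            space_group="P1",
            z_prime=len(mols),
            energy=out.energy,
        )
    return out


def niggli_reset(structure: CrystalStructure) -> CrystalStructure:
    """Re-express a P1 structure in its Niggli-reduced cell (same crystal)."""
    reduced, P = niggli_reduce(structure.lattice)
    Pinv = np.linalg.inv(P)
    mols = [
        MoleculeInstance(m.frac_position @ Pinv, m.orientation)
        for m in structure.molecules
    ]
    return replace(structure, lattice=reduced, molecules=tuple(mols))
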