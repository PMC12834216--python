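"""Rigid-molecule definition.

A molecule is treated as a rigid body throughout: a fixed set of atoms with
Cartesian coordinates in a body-fixed frame whose origin is the centroid.
Each atom carries an element symbol, a point charge (elementary-charge
units) and an atom-type label used to look up pair-potential parameters.
"""
from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = ["RigidMolecule"]

_CENTROID_TOL = 1e-9


@dataclass(frozen=True)
class RigidMolecule:
    """A rigid molecule in its body frame (centroid at the origin).

    Parameters
    ----------
    atom_elements : sequence of str
        Element symbols, one per atom.
    local_coords : (n, 3) array
        Cartesian coordinates (A) in the body frame; centroid must be zero.
    charges : (n,) array
        Point charges in elementary-charge units.
    atom_types : sequence of str
        Potential atom-type labels (e.g. ``"C_ar"``, ``"H"``).
    """

    atom_elements: tuple[str, ...]
    local_coords: np.ndarray
    charges: np.ndarray
    atom_types: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.local_coords, dtype=float))
        charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        elements = tuple(self.atom_elements)
        types = tuple(self.atom_types)
        n = len(elements)
        if coords.shape != (n, 3):
            raise ValueError(f"local_coords shape {coords.shape} != ({n}, 3)")
        if charges.shape != (n,) or len(types) != n:
            raise ValueError("per-atom arrays must all have the same length")
        for sym in elements:
            if gemmi.Element(sym).name == "X":  # gemmi maps unknown symbols to X
                raise ValueError(f"invalid element symbol {sym!r}")
        centroid = coords.mean(axis=0)
        if np.linalg.norm(centroid) > _CENTROID_TOL:
            raise ValueError(
                f"centroid of local_coords must be at the origin (|c| = "
                f"{np.linalg.norm(centroid):.2e} A); recentre the molecule first"
            )
        object.__setattr__(self, "atom_elements", elements)
        object.__setattr__(self, "local_coords", coords)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "atom_types", types)

    @classmethod
    def from_coords(cls, atom_elements, coords, charges, atom_types) -> "RigidMolecule":
        """Build a molecule from arbitrary coordinates, recentring on the centroid."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return cls(tuple(atom_elements), coords - coords.mean(axis=0),
                   np.asarray(charges, dtype=float), tuple(atom_types))

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def mass(self) -> float:
        """Molecular mass in g/mol."""
        return float(sum(gemmi.Element(e).weight for e in self.atom_elements))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def radius(self) -> float:
        """Largest atom distance from the centroid (A)."""
        return float(np.linalg.norm(self.local_coords, axis=1).max(initial=0.0))

    # -- persistence ----------------------------------------------------

    def to_file(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "atom_elements": list(self.atom_elements),
                    "local_coords": self.local_coords.tolist(),
                    "charges": self.charges.tolist(),
                    "atom_types": list(self.atom_types),
                },
                indent=1,
            )
        )

    @classmethod
    def from_file(cls, path) -> "RigidMolecule":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls.from_coords(
            tuple(d["atom_elements"]),
            np.array(d["local_coords"]),
            np.array(d["charges"]),
            tuple(d["atom_types"]),
        )

    def plane_rms(self) -> float:
        """RMS deviation (A) of the atoms from their best-fit plane."""
        _, s, _ = np.linalg.svd(self.local_coords, full_matrices=False)
        return float(s[2] / np.sqrt(self.n_atoms))

    def plane_normal(self) -> np.ndarray:
        """Unit normal of the best-fit plane through the atoms (body frame)."""
        _, _, vt = np.linalg.svd(self.local_coords, full_matrices=False)
        return vt[2]
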