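"""Minimal-core CIF input/output for rigid-molecule crystals.

Structures are written as P1 CIFs (cell parameters, a trivial symmetry
loop, fractional atom sites).  Reading recovers the rigid-body description:
atoms are grouped into whole molecules by a covalent-radius bond criterion
with minimum-image unwrapping, matched to the reference molecule by bond
graph isomorphism, and each molecule's position and orientation are fitted
by least squares.
"""
from __future__ import annotations

from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .lattice import Lattice
from .molecule import RigidMolecule
from .structure import CrystalStructure, MoleculeInstance

__all__ = ["read_cif", "write_cif", "CifParseError", "CompositionError"]

BOND_SCALE = 1.2  # bond if d < BOND_SCALE * (r_cov_i + r_cov_j)
FIT_TOL = 1e-3  # A, max RMSD of the rigid-body fit on read


class CifParseError(ValueError):
    """The file is not a CIF we can interpret."""


class CompositionError(ValueError):
    """The CIF atoms cannot be partitioned into copies of the reference molecule."""


def write_cif(structure: CrystalStructure, path: str | Path) -> None:
    """Write a P1 CIF with every atom of every molecule as a fractional site."""
    a, b, c, al, be, ga = structure.lattice.parameters
    lines = [
        "data_crystalmct",
        f"_cell_length_a    {a:.8f}",
        f"_cell_length_b    {b:.8f}",
        f"_cell_length_c    {c:.8f}",
        f"_cell_angle_alpha {al:.8f}",
        f"_cell_angle_beta  {be:.8f}",
        f"_cell_angle_gamma {ga:.8f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "_symmetry_Int_Tables_number 1",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x, y, z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    ref = structure.molecule_ref
    cart = structure.atom_coords_cart()
    counter: dict[str, int] = {}
    for i in range(structure.n_molecules):
        frac = structure.lattice.to_fractional(cart[i]) % 1.0
        for j, el in enumerate(ref.atom_elements):
            counter[el] = counter.get(el, 0) + 1
            lines.append(
                f"{el}{counter[el]} {el} {frac[j, 0]:.8f} {frac[j, 1]:.8f} {frac[j, 2]:.8f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_sites(path: str | Path) -> tuple[Lattice, list[str], np.ndarray]:
    try:
        doc = gemmi.cif.read_file(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi error messages carry the line number
        raise CifParseError(f"malformed CIF {path}: {exc}") from exc

    def need(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise CifParseError(f"CIF {path} is missing {tag}")
        return float(gemmi.cif.as_number(val))

    params = [need(f"_cell_length_{x}") for x in "abc"] + [
        need(f"_cell_angle_{x}") for x in ("alpha", "beta", "gamma")
    ]
    try:
        lattice = Lattice.from_parameters(*params)
    except ValueError as exc:
        raise CifParseError(f"CIF {path} has a degenerate cell: {exc}") from exc
    table = block.find(
        "_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    if len(table) == 0:
        raise CifParseError(f"CIF {path} has no _atom_site_ loop with fractional coordinates")
    elements, frac = [], []
    for row in table:
        elements.append(gemmi.cif.as_string(row[0]))
        frac.append([gemmi.cif.as_number(row[i]) for i in (1, 2, 3)])
    return lattice, elements, np.array(frac, dtype=float)


def _bond_graph(elements: list[str], coords: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    radii = np.array([gemmi.Element(e).covalent_r for e in elements])
    for i, e in enumerate(elements):
        g.add_node(i, element=e)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = BOND_SCALE * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((d < cut) & ~np.eye(len(elements), dtype=bool))
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    return g


def _unwrap_components(
    lattice: Lattice, elements: list[str], frac: np.ndarray
) -> list[tuple[list[int], np.ndarray]]:
    """Group atoms into bonded molecules, unwrapping across cell boundaries."""
    n = len(elements)
    radii = np.array([gemmi.Element(e).covalent_r for e in elements])
    # periodic bond graph on minimum-image distances
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        df = frac - frac[i]
        df -= np.round(df)
        d = np.linalg.norm(df @ lattice.matrix, axis=1)
        cut = BOND_SCALE * (radii + radii[i])
        for j in np.nonzero((d < cut))[0]:
            if j != i:
                adj[i].append(int(j))
    seen = np.zeros(n, dtype=bool)
    groups = []
    for start in range(n):
        if seen[start]:
            continue
        # BFS, placing each newly-reached atom at the minimum image of its parent
        idx = [start]
        pos = {start: frac[start].copy()}
        seen[start] = True
        queue = [start]
        while queue:
            i = queue.pop(0)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    df = frac[j] - frac[i]
                    df -= np.round(df)
                    pos[j] = pos[i] + df
                    idx.append(j)
                    queue.append(j)
        groups.append((idx, np.array([pos[i] for i in idx])))
    return groups


def read_cif(path: str | Path, molecule: RigidMolecule) -> CrystalStructure:
    """Read a P1 CIF and recover rigid-body placements of ``molecule``.

    Raises :class:`CifParseError` for unreadable files and
    :class:`CompositionError` when the atoms do not form whole copies of the
    reference molecule (wrong composition, distorted geometry, or a mirror
    image of a chiral reference).
    """
    lattice, elements, frac = _parse_sites(path)
    ref_graph = _bond_graph(list(molecule.atom_elements), molecule.local_coords)
    groups = _unwrap_components(lattice, elements, frac)
    instances = []
    for idx, gfrac in groups:
        if len(idx) != molecule.n_atoms:
            raise CompositionError(
                f"found a bonded group of {len(idx)} atoms; reference molecule "
                f"has {molecule.n_atoms}"
            )
        cart = lattice.to_cartesian(gfrac)
        centroid = cart.mean(axis=0)
        centered = cart - centroid
        sub_elements = [elements[i] for i in idx]
        g = _bond_graph(sub_elements, centered)
        matcher = nx.algorithms.isomorphism.GraphMatcher(
            g, ref_graph, node_match=lambda u, v: u["element"] == v["element"]
        )
        best: tuple[float, Rotation] | None = None
        for n_iso, mapping in enumerate(matcher.isomorphisms_iter()):
            if n_iso >= 500:
                break
            order = np.empty(molecule.n_atoms, dtype=int)
            for found_i, ref_i in mapping.items():
                order[ref_i] = found_i
            rot, rssd = Rotation.align_vectors(centered[order], molecule.local_coords)
            rmsd = rssd / np.sqrt(molecule.n_atoms)
            if best is None or rmsd < best[0]:
                best = (rmsd, rot)
        if best is None or best[0] > FIT_TOL:
            detail = "no bond-graph match" if best is None else f"best fit RMSD {best[0]:.2e} A"
            raise CompositionError(
                f"a bonded group could not be fitted to the reference molecule ({detail})"
            )
        instances.append(
            MoleculeInstance.from_rotation(lattice.to_fractional(centroid), best[1])
        )
    if not instances:
        raise CompositionError("CIF contains no atoms")
    return CrystalStructure(
        lattice=lattice,
        molecules=tuple(instances),
        molecule_ref=molecule,
        space_group="P1",
        z_prime=len(instances),
    )
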