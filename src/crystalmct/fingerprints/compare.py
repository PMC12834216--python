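"""Packing-shell comparison and two-stage duplicate clustering.

The packing-shell descriptor summarises a molecule's local coordination:
sorted centroid distances and interplanar angles to its n nearest
neighbours (periodic images included).  Two structures match when some
choice of central molecule in each gives element-wise agreement of both
lists within tolerance.  This is a simplified stand-in for full
15-molecule RMSD overlay comparisons: it is free of any external API,
invariant to supercells and cell re-settings, and discriminative enough to
confirm or refute the fast powder-pattern pre-screen.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core.structure import CrystalStructure
from .pxrd import PxrdPattern, pattern_similarity, simulate_pxrd

__all__ = [
    "PackingShellDescriptor",
    "packing_shell_descriptor",
    "packing_shell_compare",
    "cluster_structures",
]

N_NEIGHBOURS = 14


@dataclass(frozen=True)
class PackingShellDescriptor:
    """Sorted neighbour centroid distances (A) and interplanar angles (deg)."""

    distances: np.ndarray
    angles: np.ndarray  # in [0, 90], same neighbour order as distances


def _neighbour_shell(structure: CrystalStructure, center: int, n: int):
    """(distance, neighbour index, image) for the n nearest neighbours."""
    H = structure.lattice.matrix
    frac = np.array([m.frac_position for m in structure.molecules])
    M = len(frac)
    shells = 1
    while True:
        rng = np.arange(-shells, shells + 1)
        imgs = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
        d = (frac[None, :, :] + imgs[:, None, :] - frac[center]) @ H  # (ni, M, 3)
        dist = np.linalg.norm(d, axis=-1).ravel()
        order = np.argsort(dist, kind="stable")
        # drop self (distance 0)
        order = order[dist[order] > 1e-9]
        if len(order) >= n:
            # anything outside the enumerated box is at least `shells` cell
            # heights away; accept once the n-th neighbour is closer than that
            r_n = dist[order[n - 1]]
            V = abs(np.linalg.det(H))
            heights = V / np.array([
                np.linalg.norm(np.cross(H[1], H[2])),
                np.linalg.norm(np.cross(H[0], H[2])),
                np.linalg.norm(np.cross(H[0], H[1])),
            ])
            if r_n < shells * heights.min() or shells >= 6:
                sel = order[:n]
                ni = sel // M
                mi = sel % M
                return dist[sel], mi, imgs[ni]
        shells += 1
        if shells > 8:
            raise RuntimeError("could not build a neighbour shell; degenerate cell")


def packing_shell_descriptor(
    structure: CrystalStructure, center: int = 0, n: int = N_NEIGHBOURS
) -> PackingShellDescriptor:
    dist, mi, _ = _neighbour_shell(structure, center, n)
    normal_body = structure.molecule_ref.plane_normal()
    normals = np.array(
        [m.rotation_matrix @ normal_body for m in structure.molecules]
    )
    cosang = np.abs(normals[mi] @ normals[center])
    angles = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return PackingShellDescriptor(dist, angles)


def packing_shell_compare(
    a: CrystalStructure,
    b: CrystalStructure,
    tol_dist: float = 0.3,
    tol_angle: float = 5.0,
    n: int = N_NEIGHBOURS,
) -> tuple[bool, float]:
    """Compare packing shells, maximising over the central-molecule choice.

    Returns (match, distance) where distance is the smallest over centre
    pairs of max(|delta d|/tol_dist, |delta angle|/tol_angle); a match is
    distance <= 1.
    """
    desc_a = [packing_shell_descriptor(a, i, n) for i in range(a.n_molecules)]
    desc_b = [packing_shell_descriptor(b, j, n) for j in range(b.n_molecules)]
    best = np.inf
    for da in desc_a:
        for db in desc_b:
            dd = np.abs(da.distances - db.distances).max() / tol_dist
            dang = np.abs(da.angles - db.angles).max() / tol_angle
            best = min(best, max(dd, dang))
    return bool(best <= 1.0), float(best)


def cluster_structures(
    structures: list[CrystalStructure],
    pxrd_threshold: float = 0.98,
    confirm: bool = True,
    patterns: list[PxrdPattern] | None = None,
    ell: float = 1.5,
) -> tuple[list[list[int]], list[int]]:
    """Two-stage duplicate clustering.

    Single-linkage clusters on powder-pattern similarity >= threshold; with
    ``confirm``, each cluster is re-examined with the packing-shell
    comparator against its lowest-energy member and split as needed.
    Returns (clusters as index lists, representative index per cluster),
    with clusters ordered by their representative's energy (None-energy
    structures last, ties by index).
    """
    if not structures:
        raise ValueError("no structures to cluster")
    if patterns is None:
        patterns = [simulate_pxrd(s) for s in structures]
    N = len(structures)
    parent = list(range(N))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(N):
        for j in range(i + 1, N):
            if find(i) != find(j) and pattern_similarity(patterns[i], patterns[j], ell) >= pxrd_threshold:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i in range(N):
        groups.setdefault(find(i), []).append(i)

    def energy_key(i):
        e = structures[i].energy
        return (e is None, e if e is not None else 0.0, i)

    clusters: list[list[int]] = []
    for members in groups.values():
        if not confirm or len(members) == 1:
            clusters.append(sorted(members))
            continue
        remaining = sorted(members, key=energy_key)
        while remaining:
            rep = remaining[0]
            mine = [rep]
            rest = []
            for m in remaining[1:]:
                match, _ = packing_shell_compare(structures[rep], structures[m])
                (mine if match else rest).append(m)
            clusters.append(sorted(mine))
            remaining = rest
    reps = [min(c, key=energy_key) for c in clusters]
    idx = sorted(range(len(reps)), key=lambda t: energy_key(reps[t]))
    return [clusters[t] for t in idx], [reps[t] for t in idx]
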