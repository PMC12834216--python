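"""Packing-motif classification for planar molecules.

Crystals of planar aromatic molecules fall into a small set of canonical
motifs: herringbone (H, edge-to-face contacts only), sandwich-herringbone
(SH, herringbone of pi-stacked pairs), beta (layered translational
stacks) and gamma (flattened herringbone mixing stacks and edge
contacts).  Classification counts, for each molecule's nearest-neighbour
shell, "stacked" contacts (near-parallel planes at van-der-Waals stacking
separation) and "edge" contacts (large interplanar angle), and applies a
deterministic rule set over those counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core.structure import CrystalStructure
from .fingerprints.compare import N_NEIGHBOURS, _neighbour_shell

__all__ = ["MotifThresholds", "classify_motif", "contact_counts"]


@dataclass(frozen=True)
class MotifThresholds:
    """Calibration constants for motif assignment.

    stack_angle: max interplanar angle (deg) of a stacked contact;
    edge_angle: min interplanar angle (deg) of an edge contact;
    stack_sep: (min, max) distance (A) of the centroid separation projected
    on the central molecule's plane normal for a stacked contact;
    planarity: max RMS out-of-plane deviation (A) of the reference molecule.
    """

    stack_angle: float = 15.0
    edge_angle: float = 30.0
    stack_sep: tuple[float, float] = (2.0, 4.0)
    stack_max_dist: float = 6.0  # A, centroid cap: excludes far slipped neighbours
    planarity: float = 0.3
    n_neighbours: int = N_NEIGHBOURS


def contact_counts(
    structure: CrystalStructure, thresholds: MotifThresholds = MotifThresholds()
) -> list[tuple[int, int]]:
    """(n_stacked, n_edge) over the neighbour shell of every molecule."""
    t = thresholds
    normal_body = structure.molecule_ref.plane_normal()
    normals = np.array([m.rotation_matrix @ normal_body for m in structure.molecules])
    frac = np.array([m.frac_position for m in structure.molecules])
    H = structure.lattice.matrix
    out = []
    for i in range(structure.n_molecules):
        dist, mi, imgs = _neighbour_shell(structure, i, t.n_neighbours)
        vecs = (frac[mi] + imgs - frac[i]) @ H
        cosang = np.abs(normals[mi] @ normals[i])
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        perp = np.abs(vecs @ normals[i])
        stacked = (
            (ang < t.stack_angle)
            & (perp > t.stack_sep[0])
            & (perp < t.stack_sep[1])
            & (dist < t.stack_max_dist)
        )
        edge = ang > t.edge_angle
        out.append((int(stacked.sum()), int(edge.sum())))
    return out


def classify_motif(
    structure: CrystalStructure, thresholds: MotifThresholds = MotifThresholds()
) -> str:
    """One of {"H", "SH", "beta", "gamma", "other"}.

    Molecules that are not planar enough are always "other"; otherwise the
    rule set over per-molecule (stacked, edge) contact counts:

    - beta: every molecule has >= 2 stacked contacts and none has an edge
      contact (translational layers);
    - gamma: every molecule has >= 2 stacked and >= 2 edge contacts
      (flattened herringbone);
    - SH: every molecule has exactly 1 stacked partner plus >= 2 edge
      contacts (herringbone of sandwich pairs);
    - H: no stacking anywhere and >= 4 edge contacts per molecule;
    - anything else: "other".
    """
    if structure.molecule_ref.plane_rms() > thresholds.planarity:
        return "other"
    counts = contact_counts(structure, thresholds)
    ns = np.array([c[0] for c in counts])
    ne = np.array([c[1] for c in counts])
    if ns.min() >= 2 and ne.max() == 0:
        return "beta"
    if ns.min() >= 2 and ne.min() >= 2:
        return "gamma"
    if (ns == 1).all() and ne.min() >= 2:
        return "SH"
    if ns.max() == 0 and ne.min() >= 4:
        return "H"
    return "other"
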