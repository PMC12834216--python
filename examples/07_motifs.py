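"""Classify the packing motifs of planar-molecule crystals.

Builds idealised herringbone, sandwich-herringbone and stacked packings of
the toy hexagon and shows the contact-count rules behind each label.
"""
import numpy as np
from scipy.spatial.transform import Rotation

from crystalmct import CrystalStructure, Lattice, MoleculeInstance
from crystalmct.fixtures import hex1, make_two_basin_crystal_fixture
from crystalmct.motifs import classify_motif, contact_counts

molecule = hex1()
_, _, (stacked, edge) = make_two_basin_crystal_fixture()

qa = Rotation.from_euler("x", 50, degrees=True)
qb = Rotation.from_euler("x", -50, degrees=True)
herringbone = CrystalStructure(
    Lattice(np.eye(3) * 7.0),
    (MoleculeInstance(np.zeros(3), qa.as_quat()),
     MoleculeInstance(np.array([0.5, 0.5, 0.5]), qb.as_quat())),
    molecule,
)

na = qa.as_matrix() @ np.array([0, 0, 1.0])
nb = qb.as_matrix() @ np.array([0, 0, 1.0])
lat = Lattice(np.diag([9.0, 9.0, 13.0]))
pair_b = np.array([0.5, 0.5, 0.5])
sandwich = CrystalStructure(
    lat,
    (MoleculeInstance(np.zeros(3), qa.as_quat()),
     MoleculeInstance((3.4 * na) @ np.linalg.inv(lat.matrix), qa.as_quat()),
     MoleculeInstance(pair_b, qb.as_quat()),
     MoleculeInstance(pair_b + (3.4 * nb) @ np.linalg.inv(lat.matrix), qb.as_quat())),
    molecule,
)

for name, s in [("stacked reference", stacked), ("edge reference", edge),
                ("ideal herringbone", herringbone),
                ("stacked-pair herringbone", sandwich)]:
    counts = contact_counts(s)
    print(f"{name:26s} -> {classify_motif(s):6s} "
          f"(stacked, edge) contacts per molecule: {counts}")
print()
print("beta = layered pi-stacks; gamma = stacks plus edge contacts (flattened")
print("herringbone); H = edge-to-face only; SH = herringbone of stacked pairs.")
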