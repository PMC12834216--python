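"""Evaluate the lattice energy of a toy aromatic crystal.

Builds a one-molecule triclinic crystal of the hexagonal C6H6-like toy
molecule and evaluates its exp-6 + point-charge lattice energy.
"""
import numpy as np
from scipy.spatial.transform import Rotation

from crystalmct import CrystalStructure, Lattice, MoleculeInstance
from crystalmct.energy import lattice_energy
from crystalmct.fixtures import hex1, toy_potential

molecule = hex1()
potential = toy_potential()

lattice = Lattice.from_parameters(7.2, 7.4, 3.6, 90.0, 95.0, 90.0)
placement = MoleculeInstance.from_rotation(
    [0.1, 0.2, 0.3], Rotation.from_euler("xyz", [20, 10, 5], degrees=True)
)
crystal = CrystalStructure(lattice, (placement,), molecule)

report = lattice_energy(crystal, potential, clash_check=False)
print(f"density                 {crystal.density:8.3f}  g/cm^3")
print(f"repulsion-dispersion    {report.repulsion_dispersion:8.3f}  kJ/mol")
print(f"electrostatic (Ewald)   {report.electrostatic:8.3f}  kJ/mol")
print(f"lattice energy          {report.total_per_molecule:8.3f}  kJ/mol per molecule")
print()
print("A negative lattice energy means the periodic packing is bound relative")
print("to isolated molecules; the electrostatic part is small because the toy")
print("molecule carries only modest +-0.1 e charges.")
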