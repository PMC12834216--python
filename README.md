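# crystalmct

Crystal structure prediction plus Monte Carlo threshold mapping of crystal
energy landscapes for rigid organic molecules.

Conventional crystal structure prediction (CSP) enumerates the local minima
of a molecule's lattice-energy surface and ranks them, but says nothing
about the *barriers* separating those minima -- the quantity that decides
whether a metastable polymorph survives, which transformations need heat or
pressure, and why some forms only appear by recrystallisation.  This
package implements the Monte Carlo threshold (MCT) algorithm on top of a
CSP workflow: random walks confined below a rising sequence of energy lids
explore each basin, sampled configurations are quenched to local minima,
and the lid at which a minimum first appears is an upper bound on the
barrier to it.  Merging trajectories through shared minima produces a
disconnectivity tree of the whole landscape, with each minimum classified
by its packing motif (herringbone H, sandwich-herringbone SH, layered
β, flattened-herringbone γ).

It is a library for computational chemists and materials scientists
studying polymorphism: rigid molecules with atom-atom exp-6 potentials

    U(r) = A exp(-B r) - C r^-6   +   point-charge Ewald electrostatics,

analytic gradients, L-BFGS rigid-body + lattice minimisation, Sobol-sampled
symmetric structure generation in the common organic space groups,
powder-pattern fingerprints with de Gelder similarity for duplicate
removal, generalized-convex-hull selection of diverse trajectory starts,
and union-find disconnectivity analysis.  A thin `crystalmct` command-line
interface wraps the main workflows; the primary interface is the Python
API, with narrative scripts under `examples/`.

## Worked example

Evaluate the lattice energy of a one-molecule toy aromatic crystal
(`examples/01_lattice_energy.py`):

```
density                    0.679  g/cm^3
repulsion-dispersion     -22.315  kJ/mol
electrostatic (Ewald)      4.122  kJ/mol
lattice energy           -18.193  kJ/mol per molecule
```

The packing is bound (negative lattice energy) but loose; minimising it
(`examples/02_minimise_crystal.py`) densifies the cell to ~1.03 g/cm^3 and
-42.6 kJ/mol.  Bounding the barrier on an analytic double well with a known
saddle (`examples/05_threshold_double_well.py`):

```
flood-fill saddle energy: 13.300 kJ/mol (analytic: 13.300)
schedule S3: 17 lids, 34000 total moves
seed 0: far basin first found at lid 13.75 (saddle + 0.45)
seed 1: far basin first found at lid 13.75 (saddle + 0.45)
seed 2: far basin first found at lid 13.75 (saddle + 0.45)
```

The threshold walk discovers the far basin at the first lid above the true
saddle: the first-found lid is a barrier upper bound whose resolution is
the lid increment.  `examples/06_disconnectivity.py` runs the same
machinery on a real two-polymorph toy crystal and prints the merge lid
between the stacked and edge-contact packings together with the exported
newick tree; `examples/03_csp_search.py`, `04_powder_fingerprints.py` and
`07_motifs.py` cover the search, fingerprint and motif components.

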