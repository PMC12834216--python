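# Methods

`crystalmct` maps the lattice-energy landscape of a rigid organic molecule in
three stages: a crystal-structure-prediction (CSP) search enumerates local
minima; Monte Carlo threshold (MCT) trajectories bound the energy barriers
between them; a union-find sweep over the threshold lids assembles the
result into a disconnectivity tree.  This note records the models, the
parameters that matter, the numerical choices, and what the shipped
synthetic systems do and do not demonstrate.

## Energy model

The crystal is a periodic arrangement of rigid bodies: each molecule is a
fixed set of atoms with body-frame coordinates, point charges (elementary
units) and atom-type labels.  The lattice energy per molecule is

    E = 1/2 * sum over intermolecular atom pairs of
          [ A_ij exp(-B_ij r) - C_ij r^-6 ]  +  E_Coulomb

with the sum running over all periodic images within a real-space cutoff.
Parameters A (kJ/mol), B (1/A) and C (kJ/mol A^6) are looked up per
atom-type pair; missing cross terms use the standard combining rules
A_ij = sqrt(A_ii A_jj), B_ij = (B_ii + B_jj)/2, C_ij = sqrt(C_ii C_jj).
Electrostatics are point-charge Coulomb sums evaluated by Ewald summation
(real-space complement of the error function within the same cutoff,
reciprocal-space Gaussian sum, self term, rigid intramolecular exclusion,
and a neutralising-background term for charged cells).  The splitting
parameter is chosen from the requested accuracy, alpha =
sqrt(-ln eps)/r_c, with matching reciprocal cutoff; the default
eps = 1e-6 reproduces the rock-salt Madelung constant to ~1e-7 relative.
Energies are kJ/mol, lengths Angstrom, charges elementary; the Coulomb
constant is 1389.35457644382 kJ/mol A/e^2.

Three numerical details matter in practice:

- **Cutoff taper.**  The exp-6 term is switched off smoothly (C1 cubic
  taper) over the last 1 A below the cutoff, and a uniform-density r^-6
  tail correction accounts for dispersion beyond it.  A bare truncation
  would make the energy discontinuous in the coordinates and break both
  quasi-Newton line searches and finite-difference gradient checks.  The
  default cutoff is 15 A; the toy potential uses 10 A (the invariant floor
  is 8 A).
- **Soft core.**  exp-6 diverges to -infinity at r -> 0.  Below each
  pair's inner barrier radius (solved once per potential by bisection) the
  potential continues as a rising C1 quadratic, and the real-space Coulomb
  distance is floored at 0.5 A.  Monte Carlo proposals and random starting
  structures therefore get large-but-finite energies instead of crashing
  or collapsing; public energy evaluation keeps a hard 0.5 A clash error.
- **Analytic gradients.**  First derivatives with respect to fractional
  centroids, body-frame rotation charts (R -> R expm([theta]_x)) and all
  nine cell-matrix components are computed analytically, including the
  reciprocal-space cell dependence through the wave vectors and volume.
  They agree with central finite differences to ~1e-9 relative and are
  verified in the test suite on random structures.

## Local minimisation

A single-stage quasi-Newton (L-BFGS-B) minimisation over all rigid-body and
cell degrees of freedom, with the cell held lower-triangular (the crystal is
rotated into that canonical frame first; the energy is rotation-invariant).
Fractional coordinates are rescaled to Angstrom-like units so the initial
Hessian guess is roughly isotropic.  Three safeguards:

- a step-capped steepest-descent prelude (caps 0.2 A / 0.1 rad) walks badly
  strained starts into a quadratic basin before L-BFGS runs;
- each L-BFGS round is confined to a trust box (1.5 A positions, 2 A cell,
  0.6 rad rotations) around its entry point, re-centred between rounds, so
  a quench cannot line-search its way out of a shallow basin into a distant
  deeper one;
- collapsed or exploded trial cells (detected by lattice-sum size) return a
  penalty value that steers the cell lengths back.

With `fix_symmetry` the search runs over the asymmetric unit and the
crystal system's free cell parameters only; the space-group operators are
reapplied at every step.  In the canonical cell setting the Cartesian parts
of the operators are constant within a crystal system (verified at setup),
so the symmetry-chained gradient is exact.  Improper operators act on a
rigid molecule through one of its improper self-symmetries (reflection
through the molecular plane for planar molecules, inversion for
centrosymmetric ones); molecules with neither cannot sit on such positions
and are rejected.

P1 results are re-expressed in their Niggli-reduced cell (gemmi's
Krivy-Gruber reduction, with the unimodular change of basis applied to the
fractional coordinates).  Non-convergence within the iteration budget is
reported via a `converged` flag, never an exception: high-throughput
searches and MC quenches must survive pathological inputs.  The default
gradient-norm tolerance is 1e-4 (kJ/mol per coordinate unit); trajectory
quenches use 1e-3 with a reduced iteration budget, which is enough to
identify the basin and keeps campaigns affordable.

## Structure generation (CSP)

Random structures are drawn per space group from a Sobol stream (uniform
fallback): cell-length ratios in [0.5, 2], free angles in [60, 120] deg
(triclinic) or [90, 135] deg (monoclinic beta), a density target inside the
window (default 0.9-1.4 g/cm^3) that fixes the cell volume, and uniform
molecular positions and orientations (Shoemake quaternions).  Candidates
with any intermolecular contact below 1.5 A are resampled (up to 1000
attempts).  Ten common space groups plus P1 are supported with Z' = 1 or 2;
generation continues until the target number of successful minimisations
per group.  Duplicates are removed by the two-stage clustering below;
representatives are the lowest-energy cluster members and the landscape is
sorted by energy.

## Fingerprints and identity

- **Powder patterns.**  Reflections are enumerated to the resolution limit,
  intensities are |F_hkl|^2 with constant-f (atomic-number) scattering
  factors times the Lorentz-polarization factor, and peaks are broadened
  with a 0.3 deg FWHM Gaussian on a 0.05 deg grid over 5-50 deg 2theta
  (Cu K-alpha).  Patterns are invariant under supercells, cell re-settings
  and rigid translations -- precisely the equivalences identity tests must
  ignore.  Similarity is de Gelder's weighted cross-correlation with a
  1.5 deg triangular window.
- **Packing shells.**  The sorted centroid distances and interplanar angles
  of the 14 nearest neighbours, compared element-wise (0.3 A, 5 deg) and
  maximised over the central-molecule choice.  This is a deliberately
  simplified coordination-shell comparator: API-free and
  supercell/setting-invariant, used only to confirm or split the fast
  pattern clusters.
- **Clustering.**  Single-linkage on pattern similarity >= 0.98, then a
  packing-shell confirmation pass against each cluster's lowest-energy
  member.  The 0.98 threshold was calibrated once against the shipped
  fixtures (noisy copies of one packing must merge; the two engineered
  polymorphs must separate) and both calibration cases ship as tests.
- **Starting-point selection.**  Kernel PCA on the pairwise similarity
  matrix gives k = 3 structural coordinates; the lower convex hull over
  (PC_1..PC_k, energy) defines a generalized convex hull, and the
  trajectories start from the structures closest in energy to that lower
  surface within 15 kJ/mol of the global minimum (plus any must-include
  matches; the global minimum is itself always a lower-hull vertex).
  Degenerate feature sets fall back to fewer dimensions and finally to
  plain energy ranking.

## The threshold algorithm

A trajectory starts from a minimised structure expanded to a P1
Niggli-reduced sampling cell of four molecules (built by repeatedly
doubling along the shortest cell vector; cells that cannot reach exactly
four keep their size, and cells of eight or more molecules double their
move budget instead).  Moves are drawn with probabilities 0.45/0.45/0.10:

- translate one molecule by a uniform vector of norm <= 0.3 A,
- rotate one molecule by <= 15 deg about a uniform axis,
- strain the lattice by (I + eps), symmetric |eps_ij| <= 0.03, fractional
  coordinates fixed.

A move is accepted iff the new energy does not exceed the current lid
(threshold acceptance, not Metropolis).  After the per-lid move budget the
lid rises by the scheme's increment and the walker carries on from its
current configuration.  Every 25th accepted configuration (default; the
interval is a pure cost/coverage knob because quench scheduling has no RNG)
and each lid-final configuration is quenched; each quenched minimum is
registered against the campaign's shared store (energy pre-filter, then
pattern similarity), and the lid at which a minimum first appears is
recorded as its first-found lid -- an upper bound on the barrier separating
it from the start.  The per-trajectory seed is split into independent
streams for move-type choice and move geometry, so changing the quench
settings does not perturb the walk; a campaign is a pure function of its
inputs and seeds, and campaigns with an output directory are restartable
per completed trajectory.

The three shipped schemes hold 13 lids of 5.00 kJ/mol (1000 moves each,
13 000 total), 26 of 2.50 (26 000), and 17 of 1.25 up to 21.25 kJ/mol
(2000 moves each, 34 000): two coarse programs that reach high above the
start to guarantee connections, and one fine program that resolves the
low-energy barriers.

Quenched minima never feed back into the walk (walker and quencher are
independent), and the walker is never reset between lids; both choices
follow the threshold-algorithm literature's standard formulation.

## Disconnectivity analysis

Connectivity semantics: a trajectory's start is connected to every minimum
it quenched to, at that minimum's first-found lid; trajectories connect
only through shared (clustered-identical) minima; connectivity is
transitive.  Sweeping events in ascending lid order (ties broken by basin
id) with union-find yields merge events and an ultrametric tree whose
leaves are minima and whose internal nodes are merge lids.  The lid of two
minima's lowest common ancestor bounds the barrier between them from
above; never-connected basins stay in separate components.  Because merge
lids live on the schedule's lid grid, barrier resolution equals the lid
increment -- the reason the fine scheme exists.  Trees export to newick
(branch lengths are energy differences) and JSON, with an optional energy
window above the global minimum.

## Packing motifs

For planar molecules (best-fit-plane RMS below 0.3 A) each molecule's
14-neighbour shell is scanned for "stacked" contacts (interplanar angle
< 15 deg, centroid separation along the plane normal in 2-4 A, centroid
distance < 6 A -- the cap excludes far slipped neighbours that are
geometrically parallel but not in van-der-Waals contact) and "edge"
contacts (angle > 30 deg).  Deterministic rules over the per-molecule
counts assign: beta (all >= 2 stacked, no edge), gamma (all >= 2 stacked
and >= 2 edge), SH (every molecule exactly one stacked partner plus edge
contacts), H (no stacking, >= 4 edge), else "other".  The thresholds are
calibration constants in the spirit of the classical planar-aromatic
packing taxonomy; geometrically constructed archetypes of all four motifs
ship as tests.

## Synthetic systems and what they show

- **Toy molecules.**  `hex1` is a single planar hexagon (6 C at 1.40 A,
  6 H at 2.48 A, charges -0.1/+0.1 e); `hex2` a fused double hexagon with
  neutral bridgeheads.  The potential uses classic transferable
  hydrocarbon exp-6 constants (C: A = 369743, B = 3.60, C = 2439.8;
  H: A = 11971, B = 3.74, C = 136.4) with a 10 A cutoff.
- **Two-basin crystal.**  Two frozen, re-verified minima of `hex1`: a
  one-molecule translational pi-stack (beta motif, -42.619 kJ/mol) and a
  deeper two-molecule tilted packing dominated by edge contacts (gamma, a
  flattened herringbone, -46.133 kJ/mol).  Their powder similarity (0.43)
  is far below the duplicate threshold.  The toy hexagon's edge-rich
  packing minimises to gamma rather than a pure herringbone -- a property
  of the molecule, not a limitation of the classifier, which recognises
  all four motifs on constructed geometries.  The stacked basin is
  shallow: in the four-molecule sampling cell its barrier bound is a
  single fine-scheme increment (1.25 kJ/mol), so quenches from its
  neighbourhood legitimately spill into the deeper basin.
- **Analytic double well.**  E(x, y) = 13.3[(x^2-1)^2 + y^2], minima at
  (+-1, 0), single saddle of 13.3 at the origin, scaled so the fine lid
  scheme applies unchanged.  An independent flood-fill oracle (sub-level
  connectivity on a dense grid, bisected over levels) recovers the saddle
  to O(grid^2).  The surface walker's default step (0.2) is smaller than
  the inter-basin gap at every lid below the saddle, so a first-found lid
  below the saddle is geometrically impossible -- the bound property is
  structural, not statistical; landing within one increment above the
  saddle is statistical (roughly 96% of seeds).

These systems exercise every algorithmic path at desk scale.  They do not
emulate several things real crystal screens have: anisotropic repulsion,
multipole electrostatics, flexible molecules, thermal/free-energy effects,
production-scale sampling (10^4 structures per group, full-length
campaigns from ~30 starts), or experimental-pattern artefacts.  Passing
tests therefore validate the machinery -- energies, gradients, reduction,
identity, threshold bookkeeping, tree construction -- not the physical
accuracy of any particular potential.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run deliberately small instances:
50 minimised structures per space group (CSP), four starting structures
with the coarse+fine schemes and early stopping once both engineered
basins are found, quenches every 100 accepted moves, and 20-50 seeded
double-well walks.  These sizes were chosen as the smallest at which every
claimed property is exercised with margin.
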