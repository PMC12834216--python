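"""Crystal structure prediction: random symmetric generation, batch
minimisation, duplicate removal, and landscape assembly.

Candidate structures are generated in a chosen set of space groups with a
quasi-random (Sobol) stream over cell shape, molecular position and
orientation; cells are scaled to hit a target density window, clash-filtered,
lattice-energy minimised under their space-group constraints, and finally
deduplicated with the two-stage fingerprint clustering (powder-pattern
pre-screen, packing-shell confirmation).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc
from scipy.spatial.transform import Rotation

from .core.lattice import Lattice
from .core.molecule import RigidMolecule
from .core.spacegroups import CRYSTAL_SYSTEM, SEARCH_SPACE_GROUPS, get_symmetry_ops
from .core.structure import AVOGADRO, CrystalStructure, MoleculeInstance, expand_to_p1
from .core.cif import write_cif
from .energy import PotentialModel
from .fingerprints.compare import cluster_structures, packing_shell_compare
from .minimize import minimize_structure

__all__ = [
    "SearchConfig",
    "Landscape",
    "generate_random_structure",
    "run_csp",
    "match_experimental",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Structure generation kept clashing; widen the density window."""


@dataclass(frozen=True)
class SearchConfig:
    space_groups: tuple[str, ...] = ("P1", "P-1")
    z_prime: int = 1
    target_count: int = 100  # successfully minimised structures per group
    density_window: tuple[float, float] = (0.9, 1.4)  # g/cm^3
    seed: int = 0
    clash_distance: float = 1.5  # A, pre-minimisation filter
    max_attempts: int = 1000
    sampler: str = "sobol"  # or "uniform"
    energy_window: float | None = None  # kJ/mol above the global minimum
    minimize_tol: float = 1e-4

    def __post_init__(self) -> None:
        for sg in self.space_groups:
            if sg not in SEARCH_SPACE_GROUPS:
                raise ValueError(f"space group {sg!r} not in the shipped set")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        lo, hi = self.density_window
        if not 0 < lo < hi:
            raise ValueError("density window must be positive and ordered")
        if self.z_prime not in (1, 2):
            raise ValueError("z_prime must be 1 or 2")


@dataclass
class Landscape:
    """Deduplicated, energy-sorted CSP structures."""

    structures: list[CrystalStructure]
    energy_window: float | None = None
    log: dict[str, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.structures])

    def filter_window(self, window: float) -> "Landscape":
        e0 = self.energies.min()
        kept = [s for s in self.structures if s.energy <= e0 + window]
        return Landscape(kept, window, self.log)

    def to_frame(self, motifs: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.structures):
            rows.append(
                {
                    "id": i,
                    "space_group": s.space_group,
                    "energy_kJ_mol": s.energy,
                    "density_g_cm3": s.density,
                    "motif": motifs[i] if motifs else "",
                }
            )
        return pd.DataFrame(rows)

    def export(self, out_dir: str | Path, motifs: list[str] | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame(motifs).to_csv(out_dir / "landscape.csv", index=False)
        for i, s in enumerate(self.structures):
            p1 = s if s.space_group == "P1" else expand_to_p1(s)
            write_cif(p1, out_dir / f"structure_{i:04d}.cif")


def _uniform_quaternion(u: np.ndarray) -> np.ndarray:
    """Shoemake map from three uniforms to a uniform unit quaternion."""
    u1, u2, u3 = u
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array(
        [a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
         b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3)]
    )


_ANGLE_RANGES = {"triclinic": (60.0, 120.0), "monoclinic": (90.0, 135.0)}


def _sample_dim(space_group: str, z_prime: int) -> int:
    system = CRYSTAL_SYSTEM[space_group]
    n_ang = {"triclinic": 3, "monoclinic": 1, "orthorhombic": 0}[system]
    return 3 + n_ang + 1 + 6 * z_prime  # lengths, angles, density, placements


def _min_intermolecular_distance(structure: CrystalStructure) -> float:
    """Smallest atom-atom contact between different molecules/images."""
    H = structure.lattice.matrix
    coords = structure.atom_coords_cart()
    M, na, _ = coords.shape
    rng = np.arange(-1, 2)
    imgs = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    shifts = imgs @ H
    best = np.inf
    flat = coords.reshape(-1, 3)
    for a in range(M):
        for b in range(a, M):
            d = coords[b][None, :, None, :] + shifts[:, None, None, :] - coords[a][None, None, :, :]
            r = np.linalg.norm(d, axis=-1)
            if a == b:
                centre = (imgs == 0).all(axis=1)
                r[centre] = np.inf
            best = min(best, float(r.min()))
    return best


def generate_random_structure(
    molecule: RigidMolecule,
    space_group: str,
    config: SearchConfig,
    rng: np.random.Generator,
    unit_sample: np.ndarray | None = None,
) -> CrystalStructure:
    """One random symmetric structure with density inside the window and no
    intermolecular contact below ``config.clash_distance``.

    ``unit_sample`` supplies the quasi-random uniforms (one row of a Sobol
    stream); when omitted they are drawn from ``rng``.  Raises
    :class:`GenerationError` after ``config.max_attempts`` rejections.
    """
    ops = get_symmetry_ops(space_group)
    system = CRYSTAL_SYSTEM[space_group]
    n_mol_cell = len(ops) * config.z_prime
    mass_cell = n_mol_cell * molecule.mass

    dim = _sample_dim(space_group, config.z_prime)
    for _ in range(config.max_attempts):
        u = unit_sample if unit_sample is not None else rng.random(dim)
        unit_sample = None  # only usable once; retries fall back to rng
        k = 0
        ratios = 0.5 + 1.5 * u[k: k + 3]
        k += 3
        angles = [90.0, 90.0, 90.0]
        if system == "triclinic":
            lo, hi = _ANGLE_RANGES["triclinic"]
            angles = list(lo + (hi - lo) * u[k: k + 3])
            k += 3
        elif system == "monoclinic":
            lo, hi = _ANGLE_RANGES["monoclinic"]
            angles[1] = lo + (hi - lo) * u[k]
            k += 1
        rho = config.density_window[0] + (
            config.density_window[1] - config.density_window[0]
        ) * u[k]
        k += 1
        try:
            trial = Lattice.from_parameters(*ratios, *angles)
        except ValueError:
            continue  # invalid angle combination
        v_target = mass_cell / AVOGADRO / rho * 1e24  # A^3
        scale = (v_target / trial.volume) ** (1.0 / 3.0)
        lattice = Lattice(trial.matrix * scale)
        mols = []
        for z in range(config.z_prime):
            pos = u[k: k + 3]
            quat = _uniform_quaternion(u[k + 3: k + 6])
            k += 6
            mols.append(MoleculeInstance(pos, quat))
        asym = CrystalStructure(
            lattice=lattice,
            molecules=tuple(mols),
            molecule_ref=molecule,
            space_group=space_group,
            z_prime=config.z_prime,
        )
        try:
            p1 = expand_to_p1(asym) if space_group != "P1" else asym
        except ValueError:
            continue  # overlapping symmetry copies
        if _min_intermolecular_distance(p1) >= config.clash_distance:
            return asym
    raise GenerationError(
        f"no clash-free structure in {config.max_attempts} attempts for "
        f"{space_group}; widen the density window"
    )


def run_csp(
    molecule: RigidMolecule,
    potential: PotentialModel,
    config: SearchConfig,
) -> Landscape:
    """Generate, minimise and deduplicate structures for every group.

    Per group, generation continues until ``target_count`` minimisations
    succeed (converged flag set).  Failures are counted in the landscape
    log; a group whose generation keeps failing is skipped with its error
    recorded, and the other groups still run.
    """
    ss = np.random.SeedSequence(config.seed)
    all_structures: list[CrystalStructure] = []
    log: dict[str, dict[str, int]] = {}
    for sg, child in zip(config.space_groups, ss.spawn(len(config.space_groups))):
        rng = np.random.default_rng(child)
        sobol = None
        if config.sampler == "sobol":
            sobol = qmc.Sobol(_sample_dim(sg, config.z_prime),
                              seed=int(child.generate_state(1)[0] % (2**31)))
        counts = {"generated": 0, "minimised": 0, "unconverged": 0, "failed": 0}
        log[sg] = counts
        kept: list[CrystalStructure] = []
        attempts = 0
        while counts["minimised"] < config.target_count and attempts < 20 * config.target_count:
            attempts += 1
            try:
                u = sobol.random(1)[0] if sobol is not None else None
                raw = generate_random_structure(molecule, sg, config, rng, u)
            except GenerationError:
                counts["failed"] += 1
                break
            counts["generated"] += 1
            try:
                minimised = minimize_structure(
                    raw, potential, tol=config.minimize_tol,
                    fix_symmetry=(sg != "P1"),
                )
            except Exception:
                counts["failed"] += 1
                continue
            if not minimised.converged:
                counts["unconverged"] += 1
                continue
            counts["minimised"] += 1
            kept.append(minimised)
        all_structures.extend(kept)
    if not all_structures:
        raise GenerationError("no structure could be generated in any space group")
    clusters, reps = cluster_structures(all_structures)
    unique = [all_structures[r] for r in reps]
    unique.sort(key=lambda s: s.energy)
    landscape = Landscape(unique, config.energy_window, log)
    if config.energy_window is not None:
        landscape = landscape.filter_window(config.energy_window)
        landscape.log = log
    return landscape


def match_experimental(
    landscape: Landscape, reference: CrystalStructure
) -> CrystalStructure | None:
    """Landscape entry matching a (minimised) reference structure by
    packing-shell comparison, or None."""
    best = None
    best_d = np.inf
    for s in landscape.structures:
        ref_p1 = reference if reference.space_group == "P1" else expand_to_p1(reference)
        s_p1 = s if s.space_group == "P1" else expand_to_p1(s)
        match, d = packing_shell_compare(s_p1, ref_p1)
        if match and d < best_d:
            best, best_d = s, d
    return best
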