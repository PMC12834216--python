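"""The Monte Carlo threshold (MCT) algorithm.

A trajectory starts from a local minimum of the lattice-energy surface.  An
energy lid is set above the starting energy and random rigid-body/lattice
moves are proposed; a move is accepted if and only if the resulting energy
does not exceed the lid (a threshold rule, not Metropolis).  After a target
number of moves the lid is raised and the walk continues from its current
configuration.  Sampled configurations are periodically quenched (locally
minimised); the lid at which a minimum is first produced is an upper bound
on the energy barrier separating it from the start.

Three named sampling schemes are shipped: S1 and S2 reach 65 kJ/mol above
the start with 5.00 and 2.50 kJ/mol lid increments (13 000 and 26 000 total
moves), while S3 samples the low-energy region thoroughly, 2000 moves per
1.25 kJ/mol lid up to 21.25 kJ/mol (34 000 moves).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from scipy.spatial.transform import Rotation

from .core.lattice import Lattice
from .core.structure import CrystalStructure, MoleculeInstance, build_sampling_cell
from .energy import EvaluationOverflow, PotentialModel, lattice_energy
from .minima import MinimaStore
from .minimize import minimize_structure

__all__ = [
    "LidSchedule",
    "MoveParams",
    "LidRecord",
    "TrajectoryRecord",
    "make_lid_schedule",
    "propose_move",
    "run_threshold_trajectory",
    "run_mct_campaign",
    "MCTSystem",
    "CrystalSystem",
]


@dataclass(frozen=True)
class LidSchedule:
    """A lid program: equally spaced energy lids with a move budget each."""

    scheme_name: str
    lid_increment: float  # kJ/mol
    max_lid_offset: float  # kJ/mol above the starting minimum
    moves_per_lid: int

    def __post_init__(self) -> None:
        if self.lid_increment <= 0:
            raise ValueError("lid increment must be positive")
        if self.moves_per_lid < 1:
            raise ValueError("moves_per_lid must be at least 1")
        ratio = self.max_lid_offset / self.lid_increment
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"max lid offset {self.max_lid_offset} must be an integer "
                f"multiple of the increment {self.lid_increment}"
            )

    @property
    def n_lids(self) -> int:
        return int(round(self.max_lid_offset / self.lid_increment))

    @property
    def total_moves(self) -> int:
        return self.n_lids * self.moves_per_lid

    def lids(self, start_energy: float) -> list[tuple[float, int]]:
        """(lid energy, move budget) for each lid, lowest first."""
        return [
            (start_energy + k * self.lid_increment, self.moves_per_lid)
            for k in range(1, self.n_lids + 1)
        ]

    @classmethod
    def named(cls, scheme: str) -> "LidSchedule":
        table = {
            "S1": (5.00, 65.00, 1000),
            "S2": (2.50, 65.00, 1000),
            "S3": (1.25, 21.25, 2000),
        }
        if scheme not in table:
            raise KeyError(f"unknown scheme {scheme!r}; shipped schemes: S1, S2, S3")
        inc, mx, mpl = table[scheme]
        return cls(scheme, inc, mx, mpl)


def make_lid_schedule(
    scheme: str | LidSchedule, start_energy: float
) -> list[tuple[float, int]]:
    """Lid list for a named scheme (S1/S2/S3) or a custom schedule."""
    sched = LidSchedule.named(scheme) if isinstance(scheme, str) else scheme
    return sched.lids(start_energy)


@dataclass(frozen=True)
class MoveParams:
    """Monte Carlo move set: single-molecule translations and rotations,
    and symmetric lattice strains, drawn with fixed probabilities."""

    max_translation: float = 0.3  # A
    max_rotation: float = 15.0  # degrees
    max_strain: float = 0.03  # dimensionless
    move_type_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)

    def __post_init__(self) -> None:
        if min(self.max_translation, self.max_rotation, self.max_strain) < 0:
            raise ValueError("move bounds must be non-negative")
        w = np.asarray(self.move_type_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("move_type_weights must be 3 non-negative numbers summing to 1")


def propose_move(
    structure: CrystalStructure,
    params: MoveParams,
    rng: np.random.Generator,
    geom_rng: np.random.Generator | None = None,
) -> CrystalStructure:
    """One symmetric-kernel move: translate or rotate one molecule, or
    strain the lattice (fractional coordinates fixed)."""
    if geom_rng is None:
        geom_rng = rng
    u = rng.random()
    w = np.cumsum(params.move_type_weights)
    if u < w[0]:  # translate
        i = int(geom_rng.integers(structure.n_molecules))
        direction = geom_rng.normal(size=3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        step = params.max_translation * geom_rng.random() ** (1.0 / 3.0)
        df = (step * direction) @ np.linalg.inv(structure.lattice.matrix)
        mols = list(structure.molecules)
        mols[i] = MoleculeInstance(mols[i].frac_position + df, mols[i].orientation)
        return dataclasses.replace(structure, molecules=tuple(mols))
    if u < w[1]:  # rotate
        i = int(geom_rng.integers(structure.n_molecules))
        axis = geom_rng.normal(size=3)
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        angle = np.radians(params.max_rotation) * geom_rng.random()
        R = Rotation.from_quat(structure.molecules[i].orientation).as_matrix() @ \
            Rotation.from_rotvec(angle * axis).as_matrix()
        mols = list(structure.molecules)
        mols[i] = MoleculeInstance.from_rotation(
            mols[i].frac_position, Rotation.from_matrix(R)
        )
        return dataclasses.replace(structure, molecules=tuple(mols))
    # strain
    e = geom_rng.uniform(-params.max_strain, params.max_strain, size=6)
    eps = np.array(
        [[e[0], e[3], e[4]], [e[3], e[1], e[5]], [e[4], e[5], e[2]]]
    )
    H_new = structure.lattice.matrix @ (np.eye(3) + eps)
    try:
        lat = Lattice(H_new)
    except ValueError:
        return structure  # degenerate trial cell: null move
    return dataclasses.replace(structure, lattice=lat)


@dataclass
class LidRecord:
    lid: float
    accepted: int
    proposed: int
    new_minima: list[tuple[int, float]]  # (minimum id, first-found lid)


@dataclass
class TrajectoryRecord:
    trajectory_id: str
    start_minimum_id: int
    scheme_name: str
    seed: int
    lids: list[LidRecord] = field(default_factory=list)
    first_found: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "trajectory_id": self.trajectory_id,
            "start_minimum_id": self.start_minimum_id,
            "scheme_name": self.scheme_name,
            "seed": self.seed,
            "lids": [
                {"lid": l.lid, "accepted": l.accepted, "proposed": l.proposed,
                 "new_minima": [[int(i), float(f)] for i, f in l.new_minima]}
                for l in self.lids
            ],
            "first_found": {str(k): float(v) for k, v in self.first_found.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryRecord":
        rec = cls(d["trajectory_id"], d["start_minimum_id"], d["scheme_name"], d["seed"])
        rec.lids = [
            LidRecord(l["lid"], l["accepted"], l["proposed"],
                      [(int(i), float(f)) for i, f in l["new_minima"]])
            for l in d["lids"]
        ]
        rec.first_found = {int(k): float(v) for k, v in d["first_found"].items()}
        return rec


class MCTSystem(Protocol):
    """What the threshold walker needs from a sampled system."""

    def energy(self, state) -> float: ...

    def propose(self, state, type_rng: np.random.Generator,
                geom_rng: np.random.Generator): ...

    def quench(self, state) -> tuple[object, float]: ...

    def identify(self, min_state, min_energy: float) -> int: ...


class CrystalSystem:
    """Adapter running MCT on a crystal with a given potential.

    Energies use the soft-core short-range continuation so that clashing
    proposals get a finite (large) energy and are rejected by the lid rather
    than crashing the walk.
    """

    def __init__(
        self,
        potential: PotentialModel,
        params: MoveParams,
        store: MinimaStore,
        minimize_tol: float = 1e-3,
        quench_maxiter: int = 200,
        quench_rounds: int = 2,
    ):
        self.potential = potential
        self.params = params
        self.store = store
        self.minimize_tol = minimize_tol
        self.quench_maxiter = quench_maxiter
        self.quench_rounds = quench_rounds

    def energy(self, state: CrystalStructure) -> float:
        try:
            return lattice_energy(
                state, self.potential, soft_core=True, clash_check=False
            ).total_per_molecule
        except (EvaluationOverflow, ValueError):
            return np.inf

    def propose(self, state, type_rng, geom_rng):
        return propose_move(state, self.params, type_rng, geom_rng)

    def quench(self, state):
        # quenches only need to identify the basin; a moderate gradient
        # tolerance keeps the campaign affordable
        m = minimize_structure(
            state, self.potential, tol=self.minimize_tol,
            maxiter=self.quench_maxiter, rounds=self.quench_rounds,
        )
        return m, m.energy

    def identify(self, min_state, min_energy):
        return self.store.register(min_state, min_energy)


def run_threshold(
    system: MCTSystem,
    start_state,
    schedule: LidSchedule,
    seed: int,
    quench_interval: int = 25,
    trajectory_id: str = "t0",
    moves_scale: int = 1,
    stop_condition: Callable[[dict[int, float]], bool] | None = None,
) -> TrajectoryRecord:
    """Generic threshold walk over any :class:`MCTSystem`.

    The walker carries over between lids.  Every ``quench_interval``-th
    accepted configuration and each lid-final configuration is quenched and
    its minimum recorded with the current lid as first-found lid.  The RNG
    seed is split into independent streams for move-type selection and move
    geometry, so the walk itself does not depend on the quench settings.
    """
    ss = np.random.SeedSequence(seed)
    type_rng, geom_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    start_energy = system.energy(start_state)
    start_min, start_min_energy = system.quench(start_state)
    start_id = system.identify(start_min, start_min_energy)
    record = TrajectoryRecord(trajectory_id, start_id, schedule.scheme_name, seed)
    record.first_found[start_id] = start_min_energy
    current = start_state
    current_energy = start_energy
    last_quenched = start_state

    def quench_now(lid: float, lid_record: LidRecord):
        nonlocal last_quenched
        if current is last_quenched:
            return
        last_quenched = current
        try:
            min_state, min_energy = system.quench(current)
        except (EvaluationOverflow, ValueError):
            return
        mid = system.identify(min_state, min_energy)
        if mid not in record.first_found:
            record.first_found[mid] = lid
            lid_record.new_minima.append((mid, lid))

    for lid, moves in schedule.lids(start_min_energy):
        lid_record = LidRecord(lid, 0, 0, [])
        for _ in range(moves * moves_scale):
            lid_record.proposed += 1
            trial = system.propose(current, type_rng, geom_rng)
            try:
                e = system.energy(trial)
            except (EvaluationOverflow, ValueError):
                continue
            if e <= lid:
                current = trial
                current_energy = e
                lid_record.accepted += 1
                if lid_record.accepted % quench_interval == 0:
                    quench_now(lid, lid_record)
        quench_now(lid, lid_record)
        record.lids.append(lid_record)
        if stop_condition is not None and stop_condition(dict(record.first_found)):
            break
    return record


def run_threshold_trajectory(
    start: CrystalStructure,
    schedule: LidSchedule | str,
    potential: PotentialModel,
    params: MoveParams = MoveParams(),
    quench_interval: int = 25,
    seed: int = 0,
    store: MinimaStore | None = None,
    trajectory_id: str | None = None,
    minimize_tol: float = 1e-3,
    stop_condition: Callable[[dict[int, float]], bool] | None = None,
) -> tuple[TrajectoryRecord, MinimaStore]:
    """Run one MCT trajectory on a crystal.

    ``start`` must be a minimised P1 structure in its sampling cell (see
    :func:`crystalmct.core.build_sampling_cell`); cells holding eight or
    more molecules get twice the per-lid move budget.
    """
    if isinstance(schedule, str):
        schedule = LidSchedule.named(schedule)
    if store is None:
        store = MinimaStore()
    if start.space_group != "P1":
        raise ValueError("MCT sampling runs in P1; expand the structure first")
    system = CrystalSystem(potential, params, store, minimize_tol)
    moves_scale = 2 if start.n_molecules >= 8 else 1
    tid = trajectory_id or f"{schedule.scheme_name}-seed{seed}"
    record = run_threshold(
        system, start, schedule, seed, quench_interval, tid,
        moves_scale=moves_scale, stop_condition=stop_condition,
    )
    return record, store


def run_mct_campaign(
    starts: list[CrystalStructure],
    schedules: list[LidSchedule | str],
    potential: PotentialModel,
    params: MoveParams = MoveParams(),
    seeds: list[int] | int = 0,
    quench_interval: int = 25,
    store: MinimaStore | None = None,
    out_dir: str | Path | None = None,
    target_molecules: int = 4,
    minimize_tol: float = 1e-3,
    stop_condition: Callable[[dict[int, float]], bool] | None = None,
) -> tuple[list[TrajectoryRecord], MinimaStore]:
    """One trajectory per (start, schedule), sharing a minima store.

    Starts are expanded to their sampling cells here.  With ``out_dir`` the
    records and the store are written after every trajectory
    (``records.jsonl``, ``minima.json``) and completed trajectories are
    skipped on a rerun, making the campaign restartable.  Per-trajectory
    failures are isolated: the campaign continues and the failure is noted
    in the returned records list as a record with no lids.
    """
    schedules = [LidSchedule.named(s) if isinstance(s, str) else s for s in schedules]
    if isinstance(seeds, int):
        ss = np.random.SeedSequence(seeds)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(len(starts) * len(schedules))]
    if store is None:
        store = MinimaStore()
    out_dir = Path(out_dir) if out_dir is not None else None
    done: dict[str, TrajectoryRecord] = {}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        rec_path = out_dir / "records.jsonl"
        if rec_path.exists():
            for line in rec_path.read_text().splitlines():
                rec = TrajectoryRecord.from_dict(json.loads(line))
                done[rec.trajectory_id] = rec
        if (out_dir / "minima.json").exists():
            store = MinimaStore.load(out_dir / "minima.json")

    records: list[TrajectoryRecord] = []
    k = 0
    for i, start in enumerate(starts):
        try:
            cell = build_sampling_cell(start, target_molecules)
        except ValueError:
            cell = start  # sample in the original cell
        for j, sched in enumerate(schedules):
            tid = f"start{i}-{sched.scheme_name}"
            seed = seeds[k]
            k += 1
            if tid in done:
                records.append(done[tid])
                continue
            try:
                rec, _ = run_threshold_trajectory(
                    cell, sched, potential, params, quench_interval, seed,
                    store, tid, minimize_tol, stop_condition,
                )
            except Exception:
                rec = TrajectoryRecord(tid, -1, sched.scheme_name, seed)
            records.append(rec)
            if out_dir is not None:
                with open(out_dir / "records.jsonl", "a") as fh:
                    fh.write(json.dumps(rec.to_dict()) + "\n")
                store.save(out_dir / "minima.json")
    return records, store
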