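"""Merging trajectories into a minima database and a disconnectivity tree.

Connectivity semantics: a trajectory's start is connected to every minimum
it quenched to, at that minimum's first-found lid; trajectories connect to
each other only through shared (clustered-identical) minima; connectivity
is transitive.  Sweeping the lids in ascending order with union-find yields
merge events, and those events define an ultrametric tree whose leaves are
minima and whose internal nodes sit at merge lids.  The lid of the lowest
common ancestor of two minima is an upper bound on the energy barrier
separating them.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core.structure import CrystalStructure
from .fingerprints.compare import cluster_structures
from .minima import MinimaStore
from .threshold import TrajectoryRecord

__all__ = [
    "MinimaDatabase",
    "MergeEvent",
    "DisconnectivityTree",
    "assemble_minima",
    "build_disconnectivity",
    "barrier_upper_bound",
    "export_tree",
    "UNCONNECTED",
]

UNCONNECTED = float("inf")


@dataclass(frozen=True)
class MinimumEntry:
    minimum_id: int
    energy: float
    structure: CrystalStructure | None
    motif: str | None
    provenance: tuple[tuple[str, float], ...]  # (trajectory id, first-found lid)


@dataclass
class MinimaDatabase:
    """Deduplicated minima with provenance; the representative of each
    cluster is its lowest-energy member and ids are assigned in energy
    order (ties broken by a structure hash)."""

    entries: list[MinimumEntry]
    trajectory_starts: dict[str, int]  # trajectory id -> minimum id of its start
    connections: list[tuple[str, int, float]]  # (trajectory id, minimum id, lid)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e.energy for e in self.entries])

    def global_minimum(self) -> MinimumEntry:
        return min(self.entries, key=lambda e: e.energy)

    def within_window(self, window: float) -> list[MinimumEntry]:
        e0 = self.global_minimum().energy
        return [e for e in self.entries if e.energy <= e0 + window]


def _structure_hash(structure: CrystalStructure | None) -> str:
    if structure is None:
        return ""
    arr = np.round(np.sort(structure.atom_coords_cart().reshape(-1)), 6)
    return str(hash(arr.tobytes()))


def assemble_minima(
    trajectories: list[TrajectoryRecord],
    store: MinimaStore,
    pxrd_threshold: float = 0.98,
    confirm: bool = True,
    classify=None,
) -> MinimaDatabase:
    """Cluster all quenched minima across trajectories into one database.

    The store already deduplicates during the runs; this pass re-clusters
    its representatives (catching near-misses), merges provenance, and
    assigns canonical ids sorted by energy.  ``classify`` is an optional
    callable mapping a structure to a motif label.
    """
    structures = store.structures()
    if not structures:
        raise ValueError("no minima to assemble")
    patterns = [store.pattern(i) for i in range(len(store))]
    clusters, reps = cluster_structures(
        structures, pxrd_threshold, confirm, patterns=patterns
    )
    # map original store id -> cluster index
    cluster_of: dict[int, int] = {}
    for ci, members in enumerate(clusters):
        for m in members:
            cluster_of[m] = ci
    # canonical order: energy, then structure hash
    def sort_key(ci):
        rep = reps[ci]
        return (store.energy(rep), _structure_hash(structures[rep]))

    order = sorted(range(len(clusters)), key=sort_key)
    new_id = {ci: k for k, ci in enumerate(order)}

    prov: dict[int, list[tuple[str, float]]] = {k: [] for k in range(len(clusters))}
    starts: dict[str, int] = {}
    connections: list[tuple[str, int, float]] = []
    for rec in trajectories:
        if rec.start_minimum_id < 0:
            continue  # failed trajectory
        sid = new_id[cluster_of[rec.start_minimum_id]]
        starts[rec.trajectory_id] = sid
        for old, lid in sorted(rec.first_found.items()):
            mid = new_id[cluster_of[old]]
            prov[mid].append((rec.trajectory_id, lid))
            connections.append((rec.trajectory_id, mid, lid))

    entries = []
    for ci in order:
        rep = reps[ci]
        s = structures[rep]
        entries.append(
            MinimumEntry(
                minimum_id=new_id[ci],
                energy=store.energy(rep),
                structure=s,
                motif=classify(s) if classify is not None else None,
                provenance=tuple(prov[new_id[ci]]),
            )
        )
    return MinimaDatabase(entries, starts, connections)


@dataclass(frozen=True)
class MergeEvent:
    lid: float
    basins: tuple[int, int]  # representative minima ids of the merged basins


@dataclass
class _Node:
    node_id: int
    lid: float | None  # None for leaves
    energy: float | None  # None for internal nodes
    children: list[int] = field(default_factory=list)
    parent: int | None = None
    minimum_id: int | None = None


class DisconnectivityTree:
    """Ultrametric merge tree over minima.

    Leaves are minima (energies); internal nodes are merge lids.  Minima
    never connected stay in separate components ("forest" is allowed).
    """

    def __init__(self):
        self.nodes: dict[int, _Node] = {}
        self.leaf_of_minimum: dict[int, int] = {}
        self.merge_events: list[MergeEvent] = []
        self._next = 0

    # -- construction ---------------------------------------------------

    def _new_node(self, **kw) -> _Node:
        node = _Node(node_id=self._next, **kw)
        self.nodes[self._next] = node
        self._next += 1
        return node

    def add_leaf(self, minimum_id: int, energy: float) -> int:
        node = self._new_node(lid=None, energy=energy, minimum_id=minimum_id)
        self.leaf_of_minimum[minimum_id] = node.node_id
        return node.node_id

    def roots(self) -> list[int]:
        return sorted(n.node_id for n in self.nodes.values() if n.parent is None)

    def root_of(self, node_id: int) -> int:
        while self.nodes[node_id].parent is not None:
            node_id = self.nodes[node_id].parent
        return node_id

    # -- queries ---------------------------------------------------------

    def merge_lid(self, a: int, b: int) -> float:
        """Lid of the lowest common ancestor of minima a and b; +inf if
        they are in different components."""
        if a == b:
            na = self.nodes[self.leaf_of_minimum[a]]
            return float(na.energy)
        pa = self._path_to_root(self.leaf_of_minimum[a])
        nb = self.leaf_of_minimum[b]
        while nb is not None:
            if nb in pa:
                lid = self.nodes[nb].lid
                return float(lid) if lid is not None else float(self.nodes[nb].energy)
            nb = self.nodes[nb].parent
        return UNCONNECTED

    def _path_to_root(self, node_id: int) -> set[int]:
        out = set()
        while node_id is not None:
            out.add(node_id)
            node_id = self.nodes[node_id].parent
        return out

    def leaf_energies(self) -> dict[int, float]:
        return {
            n.minimum_id: n.energy for n in self.nodes.values() if n.minimum_id is not None
        }


def build_disconnectivity(
    db: MinimaDatabase, lid_grid: list[float] | np.ndarray | None = None
) -> DisconnectivityTree:
    """Union-find sweep over ascending lids.

    ``lid_grid`` defaults to the sorted set of lids appearing in the
    database's connections; every connection lid must lie on the grid.
    Equal-lid events are processed in ascending basin-id order for
    determinism.
    """
    if len(db) == 0:
        raise ValueError("empty minima database")
    tree = DisconnectivityTree()
    for e in db.entries:
        tree.add_leaf(e.minimum_id, e.energy)

    parent = {e.minimum_id: e.minimum_id for e in db.entries}
    subtree_top = {e.minimum_id: tree.leaf_of_minimum[e.minimum_id] for e in db.entries}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # group connections by trajectory: each trajectory links its start to
    # each found minimum at that minimum's first-found lid
    events: list[tuple[float, int, int]] = []
    for tid, mid, lid in db.connections:
        start = db.trajectory_starts[tid]
        if mid != start:
            events.append((lid, min(start, mid), max(start, mid)))
    if lid_grid is not None:
        grid = sorted(float(x) for x in lid_grid)
        for lid, _, _ in events:
            if not any(abs(lid - g) <= 1e-9 for g in grid):
                raise ValueError(f"connection lid {lid} is not on the lid grid")
    events.sort()

    for lid, a, b in events:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        node = tree._new_node(lid=float(lid), energy=None)
        for r in (ra, rb):
            top = subtree_top[r]
            tree.nodes[top].parent = node.node_id
            node.children.append(top)
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        parent[hi] = lo
        subtree_top[lo] = node.node_id
        tree.merge_events.append(MergeEvent(float(lid), (lo, hi)))
    return tree


def barrier_upper_bound(tree: DisconnectivityTree, a: int, b: int):
    """(merge lid, barrier height relative to a) or (inf, inf) when the
    two minima were never connected."""
    lid = tree.merge_lid(a, b)
    if lid == UNCONNECTED:
        return UNCONNECTED, UNCONNECTED
    ea = tree.nodes[tree.leaf_of_minimum[a]].energy
    return lid, lid - ea


# --------------------------------------------------------------------------
# export

def _filter_window(tree: DisconnectivityTree, window: float) -> set[int]:
    """Leaf node-ids kept by an energy window above the global minimum."""
    energies = tree.leaf_energies()
    e0 = min(energies.values())
    return {
        tree.leaf_of_minimum[m] for m, e in energies.items() if e <= e0 + window
    }


def _newick_node(tree: DisconnectivityTree, node_id: int, keep: set[int],
                 parent_level: float | None, annotate) -> str | None:
    node = tree.nodes[node_id]
    if node.minimum_id is not None:
        if node_id not in keep:
            return None
        label = annotate(node)
        length = (parent_level - node.energy) if parent_level is not None else 0.0
        return f"{label}:{length:.6f}"
    parts = [
        s for c in node.children
        for s in [_newick_node(tree, c, keep, node.lid, annotate)] if s is not None
    ]
    if not parts:
        return None
    if len(parts) == 1:
        # pruned internal node: splice the surviving child through,
        # extending its branch length
        child = parts[0]
        name, _, length = child.rpartition(":")
        extra = (parent_level - node.lid) if parent_level is not None else 0.0
        return f"{name}:{float(length) + extra:.6f}"
    length = (parent_level - node.lid) if parent_level is not None else 0.0
    return f"({','.join(parts)}):{length:.6f}"


def export_tree(
    tree: DisconnectivityTree,
    path: str | Path,
    fmt: str = "newick",
    energy_window: float | None = None,
    motifs: dict[int, str] | None = None,
) -> None:
    """Write the tree as newick (branch lengths in kJ/mol) or JSON.

    ``energy_window`` drops leaves above global-minimum + window and prunes
    internal nodes left empty.  ``motifs`` maps minimum id -> label and is
    appended to leaf names.
    """
    path = Path(path)
    if fmt == "newick":
        keep = (
            _filter_window(tree, energy_window)
            if energy_window is not None
            else set(tree.leaf_of_minimum.values())
        )

        def annotate(node: _Node) -> str:
            label = f"m{node.minimum_id}_E{node.energy:.3f}"
            if motifs and node.minimum_id in motifs:
                label += f"_{motifs[node.minimum_id]}"
            return label

        lines = []
        for root in tree.roots():
            s = _newick_node(tree, root, keep, None, annotate)
            if s is not None:
                name, _, _ = s.rpartition(":")
                lines.append(name + ";")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        data = {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "lid": n.lid,
                    "energy": n.energy,
                    "children": n.children,
                    "parent": n.parent,
                    "minimum_id": n.minimum_id,
                }
                for n in tree.nodes.values()
            ],
            "merge_events": [
                {"lid": e.lid, "basins": list(e.basins)} for e in tree.merge_events
            ],
        }
        if motifs:
            data["motifs"] = {str(k): v for k, v in motifs.items()}
        path.write_text(json.dumps(data, indent=1))
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'newick' or 'json'")


def tree_from_json(path: str | Path) -> DisconnectivityTree:
    """Reconstruct a tree exported with ``fmt='json'``."""
    data = json.loads(Path(path).read_text())
    tree = DisconnectivityTree()
    for nd in data["nodes"]:
        node = _Node(
            node_id=nd["node_id"], lid=nd["lid"], energy=nd["energy"],
            children=list(nd["children"]), parent=nd["parent"],
            minimum_id=nd["minimum_id"],
        )
        tree.nodes[node.node_id] = node
        if node.minimum_id is not None:
            tree.leaf_of_minimum[node.minimum_id] = node.node_id
        tree._next = max(tree._next, node.node_id + 1)
    tree.merge_events = [
        MergeEvent(e["lid"], tuple(e["basins"])) for e in data["merge_events"]
    ]
    return tree
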