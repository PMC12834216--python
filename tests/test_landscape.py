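"""Minima assembly, union-find disconnectivity, barriers, motifs, exports."""
import numpy as np
import pytest

from crystalmct.landscape import (
    UNCONNECTED,
    DisconnectivityTree,
    MinimaDatabase,
    MinimumEntry,
    assemble_minima,
    barrier_upper_bound,
    build_disconnectivity,
    export_tree,
    tree_from_json,
)


def make_db(energies, starts, connections):
    """Hand-built database: energies per minimum id, trajectory starts,
    (trajectory, minimum, lid) connections."""
    entries = [
        MinimumEntry(i, float(e), None, None, ())
        for i, e in enumerate(energies)
    ]
    return MinimaDatabase(entries, dict(starts), list(connections))


def brute_force_merge_lid(n, starts, connections, a, b, lids):
    """Oracle: at each lid, build the connectivity graph by transitive
    closure and report the first lid where a and b are connected."""
    for lid in sorted(lids):
        adj = {i: set() for i in range(n)}
        for tid, mid, l in connections:
            if l <= lid + 1e-12:
                s = starts[tid]
                adj[s].add(mid)
                adj[mid].add(s)
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if b in seen:
            return lid
    return UNCONNECTED


class TestBuildDisconnectivity:
    def test_single_merge(self):
        db = make_db([-10.0, -9.0], {"t0": 0, "t1": 1},
                     [("t0", 1, -5.0), ("t1", 0, -4.0)])
        tree = build_disconnectivity(db)
        assert tree.merge_lid(0, 1) == -5.0

    def test_transitive_merge_lid(self):
        # basins 0-1 merge at 10, 1-2 at 20: 0-2 must merge at 20
        db = make_db(
            [0.0, 1.0, 2.0],
            {"t0": 0, "t1": 1, "t2": 2},
            [("t0", 1, 10.0), ("t1", 2, 20.0)],
        )
        tree = build_disconnectivity(db)
        assert tree.merge_lid(0, 2) == 20.0
        assert tree.merge_lid(0, 1) == 10.0

    def test_unconnected_components_stay_separate(self):
        db = make_db([0.0, 1.0, 5.0], {"t0": 0, "t1": 1, "t2": 2},
                     [("t0", 1, 10.0)])
        tree = build_disconnectivity(db)
        assert tree.merge_lid(0, 1) == 10.0
        assert tree.merge_lid(0, 2) == UNCONNECTED
        assert len(tree.roots()) == 2

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            n_traj = int(rng.integers(1, 6))
            starts = {f"t{k}": int(rng.integers(n)) for k in range(n_traj)}
            connections = []
            lids = []
            for k in range(n_traj):
                for _ in range(int(rng.integers(1, 8))):
                    mid = int(rng.integers(n))
                    lid = float(np.round(rng.uniform(0, 30), 2)) + 10.0
                    connections.append((f"t{k}", mid, lid))
                    lids.append(lid)
            energies = rng.uniform(-5, 9.9, n)
            db = make_db(energies, starts, connections)
            tree = build_disconnectivity(db)
            pairs = rng.integers(0, n, size=(5, 2))
            for a, b in pairs:
                a, b = int(a), int(b)
                if a == b:
                    continue
                expected = brute_force_merge_lid(n, starts, connections, a, b, lids)
                assert tree.merge_lid(a, b) == pytest.approx(expected)

    def test_ultrametric_inequality_all_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            starts = {f"t{k}": int(rng.integers(n)) for k in range(3)}
            connections = [
                (f"t{k}", int(rng.integers(n)), float(rng.integers(10, 40)))
                for k in range(3) for _ in range(5)
            ]
            db = make_db(rng.uniform(0, 9, n), starts, connections)
            tree = build_disconnectivity(db)
            for a in range(n):
                for b in range(a + 1, n):
                    for c in range(b + 1, n):
                        ab = tree.merge_lid(a, b)
                        bc = tree.merge_lid(b, c)
                        ac = tree.merge_lid(a, c)
                        assert ac <= max(ab, bc) + 1e-9

    def test_merge_lids_above_leaf_energies(self):
        rng = np.random.default_rng(2)
        n = 12
        starts = {f"t{k}": int(rng.integers(n)) for k in range(3)}
        connections = [
            (f"t{k}", int(rng.integers(n)), float(rng.integers(10, 40)))
            for k in range(3) for _ in range(6)
        ]
        db = make_db(rng.uniform(0, 9, n), starts, connections)
        tree = build_disconnectivity(db)
        for a in range(n):
            for b in range(a + 1, n):
                lid = tree.merge_lid(a, b)
                if lid != UNCONNECTED:
                    ea = tree.nodes[tree.leaf_of_minimum[a]].energy
                    eb = tree.nodes[tree.leaf_of_minimum[b]].energy
                    assert lid >= max(ea, eb)


class TestBarriers:
    def test_self_barrier_is_zero(self):
        db = make_db([-10.0, -9.0], {"t0": 0, "t1": 1},
                     [("t0", 1, -5.0)])
        tree = build_disconnectivity(db)
        lid, height = barrier_upper_bound(tree, 0, 0)
        assert lid == -10.0 and height == 0.0

    def test_height_arithmetic(self):
        db = make_db([-100.0, -80.0], {"t0": 0, "t1": 1}, [("t0", 1, -60.0)])
        tree = build_disconnectivity(db)
        lid, height = barrier_upper_bound(tree, 0, 1)
        assert lid == -60.0 and height == 40.0
        lid_b, height_b = barrier_upper_bound(tree, 1, 0)
        assert lid_b == lid and height_b == 20.0

    def test_unconnected_marker(self):
        db = make_db([0.0, 1.0], {"t0": 0, "t1": 1}, [])
        tree = build_disconnectivity(db)
        assert barrier_upper_bound(tree, 0, 1) == (UNCONNECTED, UNCONNECTED)

    def test_adding_trajectories_never_raises_barriers(self):
        rng = np.random.default_rng(3)
        n = 10
        starts = {}
        connections = []
        previous = {}
        for k in range(6):
            starts[f"t{k}"] = int(rng.integers(n))
            for _ in range(4):
                connections.append(
                    (f"t{k}", int(rng.integers(n)), float(rng.integers(10, 40)))
                )
            db = make_db(np.linspace(0, 9, n), dict(starts), list(connections))
            tree = build_disconnectivity(db)
            for a in range(n):
                for b in range(a + 1, n):
                    lid = tree.merge_lid(a, b)
                    key = (a, b)
                    if key in previous:
                        assert lid <= previous[key] + 1e-9
                    previous[key] = lid


class TestExport:
    def build_tree(self):
        db = make_db([-46.0, -43.0, -41.0], {"t0": 0, "t1": 1, "t2": 2},
                     [("t0", 1, -40.0), ("t1", 2, -35.0)])
        return build_disconnectivity(db)

    def test_single_leaf_newick(self, tmp_path):
        db = make_db([-10.0], {"t0": 0}, [])
        tree = build_disconnectivity(db)
        path = tmp_path / "one.nwk"
        export_tree(tree, path, "newick")
        text = path.read_text().strip()
        assert text.startswith("m0_E-10.000")
        assert text.endswith(";")

    def test_window_filter_keeps_global_minimum(self, tmp_path):
        tree = self.build_tree()
        path = tmp_path / "w.nwk"
        export_tree(tree, path, "newick", energy_window=1.0)
        text = path.read_text()
        assert "m0_" in text
        assert "m1_" not in text and "m2_" not in text

    def test_json_round_trip(self, tmp_path):
        tree = self.build_tree()
        path = tmp_path / "t.json"
        export_tree(tree, path, "json")
        back = tree_from_json(path)
        for a in range(3):
            for b in range(3):
                assert back.merge_lid(a, b) == tree.merge_lid(a, b)

    def test_unknown_format_rejected(self, tmp_path):
        tree = self.build_tree()
        with pytest.raises(ValueError):
            export_tree(tree, tmp_path / "x", "xml")

    def test_newick_has_branch_lengths(self, tmp_path):
        tree = self.build_tree()
        path = tmp_path / "t.nwk"
        export_tree(tree, path, "newick")
        text = path.read_text()
        # leaf 0 hangs from the -35 node via the -40 node: length 5 then 6
        assert ":5.000000" in text
        assert ":6.000000" in text


class TestAssembleMinima:
    def test_degenerate_single_minimum(self, potential):
        from crystalmct.fixtures import make_two_basin_crystal_fixture
        from crystalmct.minima import MinimaStore
        from crystalmct.threshold import LidSchedule, run_threshold_trajectory
        from crystalmct.core.structure import build_sampling_cell

        # start in the deep basin with minuscule moves: the trajectory only
        # ever re-finds its start
        _, pot, (_, ref) = make_two_basin_crystal_fixture()
        cell = build_sampling_cell(ref, 4)
        from crystalmct.threshold import MoveParams

        record, store = run_threshold_trajectory(
            cell, LidSchedule("custom", 0.5, 1.0, 30), pot,
            params=MoveParams(1e-4, 0.01, 1e-5), seed=1, quench_interval=5,
        )
        db = assemble_minima([record], store)
        assert len(db) == 1
        assert db.trajectory_starts[record.trajectory_id] == 0

    def test_shared_minima_get_merged_provenance(self, potential):
        from crystalmct.fixtures import make_two_basin_crystal_fixture
        from crystalmct.minima import MinimaStore
        from crystalmct.threshold import LidSchedule, run_mct_campaign

        _, pot, (ref, _) = make_two_basin_crystal_fixture()
        sched = LidSchedule("custom", 2.5, 5.0, 60)
        records, store = run_mct_campaign(
            [ref], [sched, sched], pot, seeds=5, quench_interval=10,
        )
        db = assemble_minima(records, store)
        start_id = db.trajectory_starts[records[0].trajectory_id]
        prov_tids = {t for t, _ in db.entries[start_id].provenance}
        assert prov_tids == {r.trajectory_id for r in records}

    def test_representatives_are_distinct(self, potential):
        from crystalmct.fixtures import make_two_basin_crystal_fixture
        from crystalmct.fingerprints import pattern_similarity, simulate_pxrd
        from crystalmct.threshold import LidSchedule, run_mct_campaign

        _, pot, (refA, refB) = make_two_basin_crystal_fixture()
        sched = LidSchedule("custom", 2.5, 7.5, 80)
        records, store = run_mct_campaign(
            [refA, refB], [sched], pot, seeds=6, quench_interval=20,
        )
        db = assemble_minima(records, store)
        pats = [simulate_pxrd(e.structure) for e in db.entries]
        for i in range(len(db)):
            for j in range(i + 1, len(db)):
                assert pattern_similarity(pats[i], pats[j]) < 0.98
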