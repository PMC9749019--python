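import copy
import json

import numpy as np
import pytest

import lrdock as L
from lrdock.fixtures import make_salt_bridge_scene, make_toy_pair
from lrdock.session import Session, replay_trace
from lrdock.transforms import RigidTransform


def rigid_session(seed=0, **kw):
    rec, lig = make_toy_pair(20, 8, box=20.0, seed=seed)
    kw.setdefault("collision_mode", "overlap")
    return Session(rec, lig, **kw)


def snapshot(s: Session):
    return (copy.deepcopy(s.receptor_transform), copy.deepcopy(s.ligand_transform),
            s.deformation.copy())


class TestProposeMove:
    def test_distant_small_move_accepted(self):
        s = rigid_session(seed=1)
        s.ligand_transform = RigidTransform(np.eye(3), [100.0, 0, 0])
        ok = s.propose_move("ligand", RigidTransform(np.eye(3), [0.5, 0, 0]))
        assert ok
        assert s.ligand_transform.translation[0] == pytest.approx(100.5)

    def test_overlapping_move_rejected_state_unchanged(self):
        s = rigid_session(seed=2)
        before = snapshot(s)
        # drive the whole ligand onto the first receptor atom
        target = s.receptor.positions[0] - s.ligand.positions[0]
        ok = s.propose_move("ligand", RigidTransform(np.eye(3), target))
        assert not ok
        after = snapshot(s)
        assert np.array_equal(before[1].translation, after[1].translation)
        assert np.array_equal(before[2], after[2])
        assert s.trace[-1]["accepted"] is False

    def test_rejected_moves_never_mutate_state_random_walk(self):
        s = rigid_session(seed=3)
        rng = np.random.default_rng(7)
        for _ in range(40):
            before = snapshot(s)
            delta = RigidTransform.random(rng, max_translation=2.0,
                                          max_angle_rad=0.5)
            ok = s.propose_move("ligand" if rng.uniform() < 0.7 else "receptor",
                                delta)
            if not ok:
                after = snapshot(s)
                for b, a in zip(before, after):
                    if isinstance(b, RigidTransform):
                        assert np.array_equal(b.rotation, a.rotation)
                        assert np.array_equal(b.translation, a.translation)
                    else:
                        assert np.array_equal(b, a)

    def test_trace_grows_either_way(self):
        s = rigid_session(seed=4)
        n0 = len(s.trace)
        s.propose_move("ligand", RigidTransform(np.eye(3), [50.0, 0, 0]))
        target = s.receptor.positions[0] - s.ligand.positions[0]
        s2 = rigid_session(seed=4)
        s2.propose_move("ligand", RigidTransform(np.eye(3), target))
        assert len(s.trace) == n0 + 1 and len(s2.trace) == 1


class TestReplay:
    def test_replay_reproduces_transforms_and_energies(self, tmp_path):
        s = rigid_session(seed=5)
        rng = np.random.default_rng(11)
        for _ in range(30):
            s.propose_move("ligand" if rng.uniform() < 0.5 else "receptor",
                           RigidTransform.random(rng, max_translation=1.5,
                                                 max_angle_rad=0.4))
        path = tmp_path / "trace.jsonl"
        s.save_trace(path)
        s2 = replay_trace(*make_toy_pair(20, 8, box=20.0, seed=5), path,
                          collision_mode="overlap")
        assert np.array_equal(s.ligand_transform.rotation,
                              s2.ligand_transform.rotation)
        assert np.array_equal(s.ligand_transform.translation,
                              s2.ligand_transform.translation)
        assert np.array_equal(s.receptor_transform.rotation,
                              s2.receptor_transform.rotation)
        for a, b in zip(s.trace, s2.trace):
            assert a["accepted"] == b["accepted"]
            assert a["energy_total"] == pytest.approx(b["energy_total"],
                                                      abs=1e-9)

    def test_trace_records_are_json_lines(self, tmp_path):
        s = rigid_session(seed=6)
        s.propose_move("ligand", RigidTransform(np.eye(3), [30.0, 0, 0]))
        path = tmp_path / "t.jsonl"
        s.save_trace(path)
        recs = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(recs) == 1
        rec = recs[0]
        for key in ("step", "which", "rotation", "translation", "accepted",
                    "energy_total", "collision_mode", "collision_metric"):
            assert key in rec


class TestComponentsAndGhosts:
    def test_all_off_mask_zero_report(self):
        s = rigid_session(seed=7)
        s.set_components(False, False, False)
        rep = s.forces()
        assert rep.energy_total == 0.0
        assert np.all(rep.per_receptor_atom_force == 0)

    def test_single_component_masks_sum_to_full(self):
        s = rigid_session(seed=8)
        full = s.forces()
        total = 0.0
        for mask in ((True, False, False), (False, True, False),
                     (False, False, True)):
            s.set_components(*mask)
            total += s.forces().energy_total
        assert total == pytest.approx(full.energy_total, rel=1e-12)

    def test_mask_round_trip_restores_deformation(self):
        s = make_salt_bridge_scene()
        s.relax()
        d_on = s.deformation.copy()
        s.set_components(electrostatic=False)
        s.relax()
        assert np.abs(s.deformation - d_on).max() > 0.5
        s.set_components(electrostatic=True)
        s.relax()
        assert np.abs(s.deformation - d_on).max() < 1e-3

    def test_ghost_empty_set_identical_reports(self):
        s = rigid_session(seed=9)
        base = s.forces()
        s.set_ghost([], [])
        assert s.forces().energy_total == base.energy_total

    def test_ghost_all_receptor_atoms_zero_forces(self):
        s = rigid_session(seed=10)
        s.set_ghost(receptor_indices=range(len(s.receptor)))
        rep = s.forces()
        assert rep.pair_count == 0
        assert np.all(rep.per_receptor_atom_force == 0)

    def test_ghosting_clash_region_unblocks_move(self):
        s = rigid_session(seed=11)
        target = s.receptor.positions[0] - s.ligand.positions[0]
        delta = RigidTransform(np.eye(3), target)
        assert not s.propose_move("ligand", delta)
        pen = L.detect_overlap_collision(
            s.receptor, s.ligand,
            ligand_transform=delta.compose(s.ligand_transform))
        # ghost every receptor atom that overlaps anything in the clash pose
        s.set_ghost(receptor_indices=range(len(s.receptor)))
        assert s.propose_move("ligand", delta)
        assert pen.colliding  # the clash was real before ghosting


class TestMonitorsAndEnergyTrace:
    def test_monitor_tracks_distance(self):
        s = rigid_session(seed=12)
        m = s.add_monitor(0, 0)
        d0 = np.linalg.norm(s.receptor.positions[0] - s.ligand.positions[0])
        assert m.current == pytest.approx(d0)
        s.propose_move("ligand", RigidTransform(np.eye(3), [40.0, 0, 0]))
        assert s.trace[-1]["monitor_distances"][0] == pytest.approx(
            np.linalg.norm(s.receptor.positions[0]
                           - (s.ligand.positions[0] + [40.0, 0, 0])))

    def test_energy_trace_no_moves_single_entry(self):
        s = rigid_session(seed=13)
        trace = s.energy_trace()
        assert len(trace) == 1 and trace[0]["step"] == 0

    def test_energy_trace_matches_recomputation(self):
        s = rigid_session(seed=14)
        rng = np.random.default_rng(15)
        for _ in range(5):
            s.propose_move("ligand", RigidTransform.random(rng, 1.0, 0.3))
        series = s.energy_trace()
        s2 = replay_trace(*make_toy_pair(20, 8, box=20.0, seed=14), s.trace,
                          collision_mode="overlap")
        for a, b in zip(series, s2.energy_trace()):
            assert a["energy_total"] == pytest.approx(b["energy_total"],
                                                      abs=1e-9)


class TestMergeComplex:
    def test_atom_order_and_count(self):
        rec, lig = make_toy_pair(10, 3, seed=16)
        s = Session(rec, lig, collision_mode="overlap")
        merged = s.merge_complex()
        assert len(merged) == 13
        assert [a.name for a in merged.atoms[:10]] == [a.name for a in rec.atoms]
        assert merged.atoms[-1].serial == 13

    def test_identity_transforms_copy_coordinates(self):
        rec, lig = make_toy_pair(10, 3, seed=17)
        s = Session(rec, lig, collision_mode="overlap")
        merged = s.merge_complex()
        assert np.array_equal(merged.positions[:10], rec.positions)
        assert np.array_equal(merged.positions[10:], lig.positions)

    def test_chains_relettered(self):
        rec, lig = make_toy_pair(5, 2, seed=18)
        for a in lig.atoms:
            a.chain = "A"  # force a clash with the receptor chain
        s = Session(rec, lig, collision_mode="overlap")
        merged = s.merge_complex()
        chains = {a.chain for a in merged.atoms}
        assert len(chains) == 2

    def test_merged_reload_preserves_intramolecular_hbonds(self, tmp_path):
        s = make_salt_bridge_scene()
        merged = s.merge_complex()
        bonds_direct = L.detect_hbonds(merged, merged)
        path = tmp_path / "complex.pdb"
        L.write_pdb(merged, path)
        reloaded = L.read_structure(path)
        # carry flags over by re-assigning from the merged molecule's atoms
        for a, b in zip(reloaded.atoms, merged.atoms):
            a.is_donor, a.is_acceptor = b.is_donor, b.is_acceptor
            a.is_hydrogen = b.is_hydrogen
            a.bonded_hydrogens = list(b.bonded_hydrogens)
        reloaded.parameters_assigned = True
        bonds_reloaded = L.detect_hbonds(reloaded, reloaded)
        assert [(b.donor_index, b.acceptor_index) for b in bonds_direct] == \
               [(b.donor_index, b.acceptor_index) for b in bonds_reloaded]


class TestFlexibleSession:
    def test_flexible_move_relaxes_deformation(self):
        s = make_salt_bridge_scene()
        assert np.all(s.deformation == 0)
        ok = s.propose_move("ligand", RigidTransform(np.eye(3), [0.0, 0.0, 0.0]))
        assert ok
        assert np.abs(s.deformation).max() > 0.5

    def test_deformation_confined_to_mode_subspace(self):
        s = make_salt_bridge_scene()
        s.relax()
        V = s.response_model.V
        orth = s.deformation - V @ (V.T @ s.deformation)
        assert np.abs(orth).max() < 1e-10

    def test_world_model_frame_round_trip(self):
        s = make_salt_bridge_scene()
        rng = np.random.default_rng(19)
        s.receptor_transform = RigidTransform.random(rng, 5.0)
        f_world = rng.normal(size=(4, 3))
        R = s.receptor_transform.rotation
        back = (f_world @ R) @ R.T
        assert np.abs(back - f_world).max() < 1e-12
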