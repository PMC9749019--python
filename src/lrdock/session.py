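"""Headless docking-session engine.

A :class:`Session` holds the receptor and ligand with their rigid
transforms, evaluates nonbonded forces at every proposed move, and rejects
moves that collide (the scripted analogue of an interactive tool freezing
the molecules on contact). With a linear-response model attached, every
accepted move re-relaxes the receptor deformation to static equilibrium
under the ligand forces; flexible sessions must use force-based collision
detection.

All events append JSON-ready records to the session trace: step, which
molecule moved, the applied delta rotation/translation, acceptance, the
component energies, the collision metric, the H-bond count, and monitored
distances. A saved trace replays to a bit-identical transform history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_io import Atom, Molecule
from .collision import (DEFAULT_FORCE_THRESHOLD, CollisionReport,
                        detect_force_collision, detect_overlap_collision)
from .errors import CollisionModeError, ValidationError
from .hbond import HBondCriteria, count_intermolecular_hbonds
from .linear_response import (RelaxationSettings, ResponseModel,
                              relax_to_equilibrium)
from .nonbonded import ForceField, ForceReport, interaction_forces
from .spatial_grid import build_grid
from .transforms import RigidTransform


@dataclass
class DistanceMonitor:
    receptor_index: int
    ligand_index: int
    target_distance: float | None = None
    current: float | None = None


class Session:
    """Mutable docking-session state.

    Rejected moves leave every physical field (transforms, deformation,
    coordinates) untouched; only the trace records the attempt.
    """

    def __init__(self, receptor: Molecule, ligand: Molecule,
                 force_field: ForceField | None = None,
                 collision_mode: str = "force",
                 collision_threshold: float | None = None,
                 response_model: ResponseModel | None = None,
                 relaxation: RelaxationSettings | None = None,
                 hbond_criteria: HBondCriteria | None = None,
                 track_hbonds: bool = False):
        if collision_mode not in ("force", "overlap"):
            raise ValidationError(f"unknown collision mode {collision_mode!r}")
        if response_model is not None and collision_mode != "force":
            raise CollisionModeError(
                "a flexible receptor requires force-based collision detection")
        if response_model is not None and response_model.r_o.size != 3 * len(receptor):
            raise ValidationError("response model size does not match receptor")
        self.receptor = receptor
        self.ligand = ligand
        self.receptor_transform = RigidTransform.identity()
        self.ligand_transform = RigidTransform.identity()
        self.force_field = force_field or ForceField()
        self.collision_mode = collision_mode
        self.collision_threshold = (collision_threshold if collision_threshold
                                    is not None else
                                    (DEFAULT_FORCE_THRESHOLD
                                     if collision_mode == "force" else 0.0))
        self.response_model = response_model
        self.relaxation = relaxation or RelaxationSettings()
        self.hbond_criteria = hbond_criteria or HBondCriteria()
        self.track_hbonds = track_hbonds
        self.deformation = (np.zeros_like(response_model.r_o)
                            if response_model is not None else
                            np.zeros(3 * len(receptor)))
        self.monitors: list[DistanceMonitor] = []
        self.trace: list[dict] = []
        self._step = 0
        self._grid = build_grid(ligand.positions,
                                cell_size=self.force_field.cutoff)

    # -- geometry ----------------------------------------------------------

    def receptor_model_positions(self) -> np.ndarray:
        """Receptor coordinates in its model frame, deformation applied."""
        base = (self.response_model.r_o.reshape(-1, 3)
                if self.response_model is not None else self.receptor.positions)
        return base + self.deformation.reshape(-1, 3)

    def receptor_world_positions(self) -> np.ndarray:
        return self.receptor_transform.apply(self.receptor_model_positions())

    def ligand_world_positions(self) -> np.ndarray:
        return self.ligand_transform.apply(self.ligand.positions)

    # -- evaluation --------------------------------------------------------

    def forces(self) -> ForceReport:
        return interaction_forces(
            self.receptor, self.ligand, self.force_field,
            ligand_transform=self.ligand_transform,
            receptor_transform=self.receptor_transform,
            receptor_positions=self.receptor_model_positions(),
            grid=self._grid)

    def _collision(self, report: ForceReport | None = None) -> CollisionReport:
        if self.collision_mode == "force":
            report = report if report is not None else self.forces()
            return detect_force_collision(report, self.collision_threshold)
        return detect_overlap_collision(
            self.receptor, self.ligand,
            ligand_transform=self.ligand_transform,
            receptor_transform=self.receptor_transform,
            receptor_positions=self.receptor_model_positions(),
            cutoff=self.force_field.cutoff,
            tolerance=self.collision_threshold, grid=self._grid)

    def _model_frame_forces(self, coords_3n: np.ndarray) -> np.ndarray:
        """Ligand forces on the receptor at model coordinates ``coords_3n``,
        rotated from the world frame into the receptor model frame."""
        report = interaction_forces(
            self.receptor, self.ligand, self.force_field,
            ligand_transform=self.ligand_transform,
            receptor_transform=self.receptor_transform,
            receptor_positions=coords_3n.reshape(-1, 3),
            grid=self._grid)
        f_world = report.per_receptor_atom_force
        f_model = f_world @ self.receptor_transform.rotation  # R^T f per row
        return f_model.reshape(-1)

    def relax(self):
        """Re-relax the deformation at the current pose (no move)."""
        if self.response_model is None:
            return None
        result = relax_to_equilibrium(self.response_model,
                                      self._model_frame_forces,
                                      self.relaxation)
        self.deformation = result.deformation
        return result

    def hbond_count(self) -> int | None:
        if not self.track_hbonds:
            return None
        rec_pos = self.receptor_model_positions()
        saved = self.receptor.positions.copy()
        try:
            self.receptor.set_positions(rec_pos)
            return count_intermolecular_hbonds(
                self.receptor, self.ligand,
                receptor_transform=self.receptor_transform,
                ligand_transform=self.ligand_transform,
                criteria=self.hbond_criteria)
        finally:
            self.receptor.set_positions(saved)

    def monitor_distances(self) -> list[float]:
        rec = self.receptor_world_positions()
        lig = self.ligand_world_positions()
        out = []
        for m in self.monitors:
            m.current = float(np.linalg.norm(rec[m.receptor_index]
                                             - lig[m.ligand_index]))
            out.append(m.current)
        return out

    # -- state changes -----------------------------------------------------

    def add_monitor(self, receptor_index: int, ligand_index: int,
                    target_distance: float | None = None) -> DistanceMonitor:
        m = DistanceMonitor(int(receptor_index), int(ligand_index),
                            target_distance)
        self.monitors.append(m)
        self.monitor_distances()
        return m

    def propose_move(self, which: str, delta: RigidTransform) -> bool:
        """Apply a world-frame rigid increment to one molecule.

        The move is evaluated at the candidate pose with the configured
        collision scheme; a colliding move is rejected and the prior state
        kept. Accepted flexible moves re-relax the receptor deformation.
        Returns the acceptance flag; the trace records the attempt either
        way.
        """
        if which not in ("receptor", "ligand"):
            raise ValidationError("which must be 'receptor' or 'ligand'")
        old_rec, old_lig = self.receptor_transform, self.ligand_transform
        if which == "receptor":
            self.receptor_transform = delta.compose(old_rec)
        else:
            self.ligand_transform = delta.compose(old_lig)
        report = self.forces() if self.collision_mode == "force" else None
        coll = self._collision(report)
        accepted = not coll.colliding
        if accepted:
            if self.response_model is not None:
                self.relax()
            report = self.forces()
        else:
            self.receptor_transform, self.ligand_transform = old_rec, old_lig
            if report is None:
                report = self.forces()
        self._append_trace(which, delta, accepted, report, coll)
        return accepted

    def set_components(self, vdw_repulsive: bool | None = None,
                       vdw_attractive: bool | None = None,
                       electrostatic: bool | None = None) -> ForceField:
        """Toggle force components; later force/relaxation calls use the new
        mask."""
        self.force_field = self.force_field.with_components(
            vdw_repulsive, vdw_attractive, electrostatic)
        return self.force_field

    def set_ghost(self, receptor_indices=(), ligand_indices=(),
                  ghost: bool = True) -> None:
        """Mark atoms as ghosts: visible in structures and surfaces but
        excluded from forces, collisions and H-bonds."""
        if len(np.atleast_1d(receptor_indices)):
            self.receptor.set_ghost(receptor_indices, ghost)
        if len(np.atleast_1d(ligand_indices)):
            self.ligand.set_ghost(ligand_indices, ghost)

    # -- trace -------------------------------------------------------------

    def _append_trace(self, which, delta, accepted, report: ForceReport,
                      coll: CollisionReport):
        self._step += 1
        metric = (coll.force_magnitude if coll.mode == "force"
                  else coll.max_penetration)
        self.trace.append({
            "step": self._step,
            "which": which,
            "rotation": [float(x) for x in delta.rotation.reshape(-1)],
            "translation": [float(x) for x in delta.translation],
            "accepted": bool(accepted),
            "energy_vdw_repulsive": report.energy_vdw_repulsive,
            "energy_vdw_attractive": report.energy_vdw_attractive,
            "energy_electrostatic": report.energy_electrostatic,
            "energy_total": report.energy_total,
            "collision_mode": coll.mode,
            "collision_metric": metric,
            "collision_threshold": coll.threshold_used,
            "hbond_count": self.hbond_count(),
            "monitor_distances": self.monitor_distances(),
        })

    def energy_trace(self) -> list[dict]:
        """Time series of component energies, one entry per recorded event
        (a fresh session contributes its initial pose)."""
        if not self.trace:
            report = self.forces()
            return [{"step": 0, **{k: v for k, v in report.to_dict().items()
                                   if k.startswith("energy")}}]
        keys = ("energy_vdw_repulsive", "energy_vdw_attractive",
                "energy_electrostatic", "energy_total")
        return [{"step": rec["step"], **{k: rec[k] for k in keys}}
                for rec in self.trace]

    def save_trace(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.trace:
                fh.write(json.dumps(rec) + "\n")

    # -- export ------------------------------------------------------------

    def merge_complex(self, title: str = "complex") -> Molecule:
        """World-frame receptor (deformed) + ligand as one molecule.

        Chains are re-lettered to avoid clashes and serials renumbered; the
        result is writable as PDB and loadable as the receptor of a new
        session. Parameters and donor/acceptor flags are carried over so
        intramolecular H-bond detection works on the merged complex.
        """
        rec_world = self.receptor_world_positions()
        lig_world = self.ligand_world_positions()
        atoms: list[Atom] = []
        used_chains: list[str] = []
        chain_map: dict[tuple[str, str], str] = {}
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

        def remap(tag: str, chain: str) -> str:
            key = (tag, chain)
            if key not in chain_map:
                for letter in ([chain] if tag == "receptor" else []) + list(alphabet):
                    if letter not in used_chains:
                        chain_map[key] = letter
                        used_chains.append(letter)
                        break
            return chain_map[key]

        serial = 0
        offset = len(self.receptor)
        for tag, mol, coords, shift in (("receptor", self.receptor, rec_world, 0),
                                        ("ligand", self.ligand, lig_world, offset)):
            for a, p in zip(mol.atoms, coords):
                serial += 1
                atoms.append(Atom(
                    serial=serial, name=a.name, element=a.element,
                    residue_name=a.residue_name, residue_seq=a.residue_seq,
                    chain=remap(tag, a.chain), position=p, charge=a.charge,
                    lj_c6=a.lj_c6, lj_c12=a.lj_c12, vdw_radius=a.vdw_radius,
                    is_donor=a.is_donor, is_acceptor=a.is_acceptor,
                    is_hydrogen=a.is_hydrogen,
                    bonded_hydrogens=[h + shift for h in a.bonded_hydrogens],
                    is_ghost=a.is_ghost, insertion_code=a.insertion_code,
                    het=a.het))
        merged = Molecule(atoms, title=title)
        merged.parameters_assigned = (self.receptor.parameters_assigned
                                      and self.ligand.parameters_assigned)
        return merged


def replay_trace(receptor: Molecule, ligand: Molecule, records, **session_kwargs) -> Session:
    """Re-run a recorded move sequence on fresh molecules.

    ``records`` is the list of trace dicts (or a path to a JSON-lines file).
    Determinism of the engine guarantees an identical transform history and
    energies.
    """
    if isinstance(records, (str, Path)):
        with open(records) as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    session = Session(receptor, ligand, **session_kwargs)
    for rec in records:
        delta = RigidTransform(np.array(rec["rotation"]).reshape(3, 3),
                               np.array(rec["translation"]))
        session.propose_move(rec["which"], delta)
    return session
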