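"""Receptor-ligand collision detection.

Two schemes mirror the docking engine's contract:

* force mode (flexible receptors): the magnitude of the total interaction
  force is compared against a threshold; exceeding it is a collision.
* overlap mode (rigid docking, no parameters needed beyond vdW radii): the
  maximum interatomic penetration, max over in-cutoff pairs of
  (r_vdw_i + r_vdw_j - d_ij) floored at zero, is compared against a
  tolerance.

Both comparisons are strict (metric > threshold). Overlap mode reuses the
same 8 A cutoff grid machinery as the force kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Molecule
from .errors import ValidationError
from .nonbonded import ForceReport
from .spatial_grid import RegularGrid, build_grid
from .transforms import RigidTransform

#: Default force-collision threshold, kJ mol^-1 A^-1. An order of magnitude
#: above thermal force scales, below hard-clash forces for small ligands;
#: always configurable and recorded in session traces.
DEFAULT_FORCE_THRESHOLD = 1000.0


@dataclass
class CollisionReport:
    colliding: bool
    mode: str                       # "force" | "overlap"
    threshold_used: float
    force_magnitude: float | None = None
    max_penetration: float | None = None
    worst_pair: tuple[int, int] | None = None  # (receptor idx, ligand idx)

    def to_dict(self) -> dict:
        d = {"colliding": bool(self.colliding), "mode": self.mode,
             "threshold_used": self.threshold_used}
        if self.force_magnitude is not None:
            d["force_magnitude"] = self.force_magnitude
        if self.max_penetration is not None:
            d["max_penetration"] = self.max_penetration
            d["worst_pair"] = list(self.worst_pair) if self.worst_pair else None
        return d


def detect_force_collision(report: ForceReport,
                           threshold: float = DEFAULT_FORCE_THRESHOLD) -> CollisionReport:
    """Collision iff |total force on receptor| strictly exceeds threshold."""
    if threshold <= 0:
        raise ValidationError("force threshold must be positive")
    mag = float(np.linalg.norm(report.total_force_on_receptor))
    return CollisionReport(colliding=mag > threshold, mode="force",
                           threshold_used=threshold, force_magnitude=mag)


def detect_overlap_collision(receptor: Molecule, ligand: Molecule,
                             ligand_transform: RigidTransform | None = None,
                             receptor_transform: RigidTransform | None = None,
                             receptor_positions: np.ndarray | None = None,
                             cutoff: float = 8.0, tolerance: float = 0.0,
                             grid: RegularGrid | None = None) -> CollisionReport:
    """Maximum vdW penetration over in-cutoff pairs, ghost atoms excluded.

    Ties on the maximum break toward the lowest (receptor, ligand) index
    pair, which the ascending scan order guarantees.
    """
    r_rec = receptor.vdw_radii
    r_lig = ligand.vdw_radii
    if np.any(r_rec <= 0) or np.any(r_lig <= 0):
        raise ValidationError("vdW radii missing; assign parameters first")
    ligand_transform = ligand_transform or RigidTransform.identity()
    receptor_transform = receptor_transform or RigidTransform.identity()
    if grid is None:
        grid = build_grid(ligand.positions, cell_size=cutoff)
    rec_model = (receptor.positions if receptor_positions is None
                 else np.asarray(receptor_positions, dtype=float).reshape(-1, 3))
    rec_world = receptor_transform.apply(rec_model)
    rec_in_lig = ligand_transform.inverse().apply(rec_world)
    lig_ghost = ligand.ghost_mask
    rec_ghost = receptor.ghost_mask

    best = 0.0
    worst: tuple[int, int] | None = None
    for i in range(rec_world.shape[0]):
        if rec_ghost[i]:
            continue
        idx = grid.query_within(rec_in_lig[i], cutoff)
        if idx.size:
            idx = idx[~lig_ghost[idx]]
        if idx.size == 0:
            continue
        d = np.linalg.norm(grid.positions[idx] - rec_in_lig[i], axis=1)
        pen = r_rec[i] + r_lig[idx] - d
        k = int(np.argmax(pen))  # first occurrence = lowest ligand index
        if worst is None or pen[k] > best:
            best = float(pen[k])
            worst = (i, int(idx[k]))
    max_pen = max(best, 0.0) if worst is not None else 0.0
    return CollisionReport(colliding=max_pen > tolerance, mode="overlap",
                           threshold_used=tolerance, max_penetration=max_pen,
                           worst_pair=worst)
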