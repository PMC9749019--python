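"""Geometric hydrogen-bond detection (McDonald-Thornton criteria).

A primary hydrogen bond is a (donor D, hydrogen H, acceptor A) triple with
d(H, A) strictly below 2.5 A and the D-H...A angle strictly above 90
degrees, where the angle is measured at the hydrogen between the D->H bond
direction extended through H and the H->A direction: 180 degrees means a
perfectly linear bond. Acceptor atoms are gridded and queried around each
donor hydrogen, the same cell-list machinery the force kernel uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Molecule
from .errors import MissingHydrogensError, ValidationError
from .spatial_grid import RegularGrid, build_grid
from .transforms import RigidTransform


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 2.5   # A, strict <
    angle_cutoff: float = 90.0     # degrees, strict >

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValidationError("criteria must be positive")


@dataclass(frozen=True)
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_molecule: str            # "donor" side tag
    acceptor_molecule: str
    h_acceptor_distance: float
    donor_h_acceptor_angle: float  # degrees, 180 = linear

    def key(self):
        return (self.donor_index, self.acceptor_index, self.hydrogen_index)


def dha_angle(d_pos, h_pos, a_pos) -> float:
    """D-H...A angle at the hydrogen, degrees (180 = linear)."""
    u = np.asarray(d_pos, dtype=float) - h_pos   # H -> D
    v = np.asarray(a_pos, dtype=float) - h_pos   # H -> A
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("degenerate D-H or H-A geometry")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def detect_hbonds(donor_molecule: Molecule, acceptor_molecule: Molecule,
                  donor_transform: RigidTransform | None = None,
                  acceptor_transform: RigidTransform | None = None,
                  criteria: HBondCriteria | None = None,
                  grid: RegularGrid | None = None,
                  donor_tag: str = "donor", acceptor_tag: str = "acceptor") -> list[HBond]:
    """All hydrogen bonds donated by ``donor_molecule`` to
    ``acceptor_molecule``, sorted by (donor, acceptor) index.

    Pass the same object twice for intramolecular bonds; self-pairs
    (acceptor == donor, or acceptor covalently bonded to the hydrogen) are
    then excluded. Ghost atoms never participate. Raises
    :class:`MissingHydrogensError` when the donor molecule contains no
    hydrogens at all (e.g. an X-ray structure loaded without protons).
    """
    criteria = criteria or HBondCriteria()
    donor_transform = donor_transform or RigidTransform.identity()
    acceptor_transform = acceptor_transform or RigidTransform.identity()
    intramolecular = donor_molecule is acceptor_molecule

    donors = donor_molecule.donor_indices
    if not donor_molecule.hydrogen_mask.any():
        raise MissingHydrogensError(
            "no hydrogens present in the donor molecule; hydrogen placement "
            "must happen before H-bond detection")

    acceptors = acceptor_molecule.acceptor_indices
    acc_ghost = acceptor_molecule.ghost_mask
    acceptors = acceptors[~acc_ghost[acceptors]]
    if acceptors.size == 0 or donors.size == 0:
        return []

    don_world = donor_transform.apply(donor_molecule.positions)
    acc_world = acceptor_transform.apply(acceptor_molecule.positions)
    acc_pos = acc_world[acceptors]
    if grid is None:
        grid = build_grid(acc_pos, cell_size=criteria.distance_cutoff)

    don_ghost = donor_molecule.ghost_mask
    bonds: list[HBond] = []
    for d in donors:
        d = int(d)
        if don_ghost[d]:
            continue
        hs = donor_molecule.atoms[d].bonded_hydrogens
        if not hs:
            raise ValidationError(f"donor atom {d} has no bonded hydrogens")
        for h in hs:
            if don_ghost[h]:
                continue
            h_pos = don_world[h]
            near = grid.query_within(h_pos, criteria.distance_cutoff)
            for k in near:
                a = int(acceptors[k])
                if intramolecular and (a == d or a == h or a in hs):
                    continue
                dist = float(np.linalg.norm(acc_pos[k] - h_pos))
                angle = dha_angle(don_world[d], h_pos, acc_pos[k])
                if dist < criteria.distance_cutoff and angle > criteria.angle_cutoff:
                    bonds.append(HBond(d, int(h), a, donor_tag, acceptor_tag,
                                       dist, angle))
    bonds.sort(key=lambda b: (b.donor_index, b.acceptor_index, b.hydrogen_index))
    return bonds


def count_intermolecular_hbonds(receptor: Molecule, ligand: Molecule,
                                receptor_transform=None, ligand_transform=None,
                                criteria: HBondCriteria | None = None) -> int:
    """Bonds in both donation directions between receptor and ligand.

    Returns 0 quietly when either side simply has nothing to offer (no
    donors on one side / no acceptors on the other); raises only when a
    donor-flagged molecule lacks hydrogens entirely.
    """
    total = 0
    for don, acc, tdon, tacc, dn, an in (
            (receptor, ligand, receptor_transform, ligand_transform,
             "receptor", "ligand"),
            (ligand, receptor, ligand_transform, receptor_transform,
             "ligand", "receptor")):
        if don.donor_indices.size == 0 or acc.acceptor_indices.size == 0:
            continue
        total += len(detect_hbonds(don, acc, donor_transform=tdon,
                                   acceptor_transform=tacc, criteria=criteria,
                                   donor_tag=dn, acceptor_tag=an))
    return total
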