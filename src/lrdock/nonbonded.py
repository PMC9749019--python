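"""Pairwise 12-6 Lennard-Jones and screened Coulomb forces between a receptor
and a rigid ligand.

Energies are kJ/mol, forces kJ mol^-1 A^-1, charges in elementary charge
units. Interactions are truncated at a strict 8 A cutoff by default (no
switching, so the potential is discontinuous at the boundary — documented).
Electrostatics default to a distance-dependent relative permittivity
eps_r(r) = D*r with D = 4 /A, the common implicit-water screening choice in
docking; a constant dielectric is available. The three energy components
(vdW repulsive c12 term, vdW attractive c6 term, electrostatic) can be
toggled individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_io import Molecule
from .errors import UnparameterizedError, ValidationError
from .spatial_grid import RegularGrid, build_grid
from .transforms import RigidTransform

#: Coulomb constant k_e, kJ mol^-1 A e^-2.
COULOMB_CONSTANT = 1389.35458

#: Minimum pair distance, A; closer pairs are clamped to avoid overflow.
MIN_PAIR_DISTANCE = 1e-6


@dataclass(frozen=True)
class DielectricModel:
    """Either distance-dependent eps_r(r) = slope*r, or constant eps_r."""
    kind: str = "distance_dependent"  # or "constant"
    slope: float = 4.0                # D, 1/A (distance-dependent)
    epsilon_r: float = 1.0            # constant model

    def __post_init__(self):
        if self.kind not in ("distance_dependent", "constant"):
            raise ValidationError(f"unknown dielectric model {self.kind!r}")
        if self.kind == "distance_dependent" and self.slope <= 0:
            raise ValidationError("dielectric slope must be positive")
        if self.kind == "constant" and self.epsilon_r < 1.0:
            raise ValidationError("constant eps_r must be >= 1")


@dataclass(frozen=True)
class ForceField:
    cutoff: float = 8.0
    dielectric: DielectricModel = field(default_factory=DielectricModel)
    combination_rule: str = "geometric"  # or "lorentz_berthelot"
    vdw_repulsive: bool = True
    vdw_attractive: bool = True
    electrostatic: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.combination_rule not in ("geometric", "lorentz_berthelot"):
            raise ValidationError(
                f"unknown combination rule {self.combination_rule!r}")

    def with_components(self, vdw_repulsive=None, vdw_attractive=None,
                        electrostatic=None) -> "ForceField":
        kw = {}
        if vdw_repulsive is not None:
            kw["vdw_repulsive"] = vdw_repulsive
        if vdw_attractive is not None:
            kw["vdw_attractive"] = vdw_attractive
        if electrostatic is not None:
            kw["electrostatic"] = electrostatic
        return replace(self, **kw)


@dataclass
class ForceReport:
    per_receptor_atom_force: np.ndarray   # N x 3, world frame
    total_force_on_receptor: np.ndarray   # 3
    energy_vdw_repulsive: float
    energy_vdw_attractive: float
    energy_electrostatic: float
    pair_count: int

    @property
    def energy_total(self) -> float:
        return (self.energy_vdw_repulsive + self.energy_vdw_attractive
                + self.energy_electrostatic)

    def to_dict(self) -> dict:
        return {
            "energy_vdw_repulsive": self.energy_vdw_repulsive,
            "energy_vdw_attractive": self.energy_vdw_attractive,
            "energy_electrostatic": self.energy_electrostatic,
            "energy_total": self.energy_total,
            "total_force_on_receptor": self.total_force_on_receptor.tolist(),
            "pair_count": self.pair_count,
        }


def zero_report(n_receptor: int) -> ForceReport:
    return ForceReport(np.zeros((n_receptor, 3)), np.zeros(3), 0.0, 0.0, 0.0, 0)


# ---------------------------------------------------------------------------
# pair kernels

def pair_lj(r: float, c6: float, c12: float):
    """(repulsive energy, attractive energy, force magnitude) for one pair.

    Force magnitude is -dE/dr; positive means repulsion along the
    interatomic axis.
    """
    if np.any(np.asarray(r) <= 0):
        raise ValidationError("pair distance must be positive")
    inv_r6 = 1.0 / np.power(r, 6)
    e_rep = c12 * inv_r6 * inv_r6
    e_att = -c6 * inv_r6
    f = (12.0 * c12 * inv_r6 * inv_r6 - 6.0 * c6 * inv_r6) / r
    return e_rep, e_att, f


def pair_coulomb(r: float, qi: float, qj: float,
                 model: DielectricModel | None = None):
    """(energy, force magnitude) for a screened Coulomb pair.

    distance-dependent: E = k_e qi qj / (D r^2), F = 2 k_e qi qj / (D r^3)
    constant:           E = k_e qi qj / (eps_r r), F = k_e qi qj / (eps_r r^2)
    """
    if np.any(np.asarray(r) <= 0):
        raise ValidationError("pair distance must be positive")
    if model is None:
        model = DielectricModel()
    qq = COULOMB_CONSTANT * (qi * qj)  # product first: exact qi<->qj symmetry
    if model.kind == "distance_dependent":
        e = qq / (model.slope * r * r)
        f = 2.0 * qq / (model.slope * r * r * r)
    else:
        e = qq / (model.epsilon_r * r)
        f = qq / (model.epsilon_r * r * r)
    return e, f


def combine_lj(c6_i, c12_i, c6_j, c12_j, rule: str = "geometric"):
    """Combine per-atom C6/C12 into pair coefficients (vectorized)."""
    c6_i = np.asarray(c6_i, dtype=float)
    c12_i = np.asarray(c12_i, dtype=float)
    c6_j = np.asarray(c6_j, dtype=float)
    c12_j = np.asarray(c12_j, dtype=float)
    if rule == "geometric":
        return np.sqrt(c6_i * c6_j), np.sqrt(c12_i * c12_j)
    # Lorentz-Berthelot on sigma/epsilon, then back to C6/C12. Atoms with a
    # zero coefficient contribute nothing (sigma undefined -> pair zeroed).
    with np.errstate(divide="ignore", invalid="ignore"):
        ok_i = (c6_i > 0) & (c12_i > 0)
        ok_j = (c6_j > 0) & (c12_j > 0)
        sig_i = np.where(ok_i, np.power(np.where(ok_i, c12_i / np.where(c6_i > 0, c6_i, 1.0), 0.0), 1 / 6), 0.0)
        sig_j = np.where(ok_j, np.power(np.where(ok_j, c12_j / np.where(c6_j > 0, c6_j, 1.0), 0.0), 1 / 6), 0.0)
        eps_i = np.where(ok_i, c6_i * c6_i / np.where(c12_i > 0, 4.0 * c12_i, 1.0), 0.0)
        eps_j = np.where(ok_j, c6_j * c6_j / np.where(c12_j > 0, 4.0 * c12_j, 1.0), 0.0)
    ok = ok_i & ok_j
    sig = 0.5 * (sig_i + sig_j)
    eps = np.sqrt(eps_i * eps_j)
    c6 = np.where(ok, 4.0 * eps * sig ** 6, 0.0)
    c12 = np.where(ok, 4.0 * eps * sig ** 12, 0.0)
    return c6, c12


# ---------------------------------------------------------------------------
# receptor-ligand kernel

def _check_parameterized(*mols: Molecule):
    bad = [m.title or f"molecule#{i}" for i, m in enumerate(mols)
           if not m.parameters_assigned]
    if bad:
        raise UnparameterizedError(
            f"parameters not assigned on: {', '.join(bad)}")


def interaction_forces(receptor: Molecule, ligand: Molecule,
                       ff: ForceField | None = None,
                       ligand_transform: RigidTransform | None = None,
                       receptor_transform: RigidTransform | None = None,
                       receptor_positions: np.ndarray | None = None,
                       grid: RegularGrid | None = None) -> ForceReport:
    """Per-receptor-atom forces and component energies within the cutoff.

    ``receptor_positions`` optionally overrides the receptor's stored (model
    frame) coordinates, e.g. with linear-response-deformed ones. Ghost atoms
    on either side are excluded. Forces are returned in the world frame; the
    total force on the ligand is the exact negative of
    ``total_force_on_receptor`` because both derive from the same pair sum.
    """
    _check_parameterized(receptor, ligand)
    ff = ff or ForceField()
    ligand_transform = ligand_transform or RigidTransform.identity()
    receptor_transform = receptor_transform or RigidTransform.identity()
    if grid is None:
        grid = build_grid(ligand.positions, cell_size=ff.cutoff)

    rec_model = (receptor.positions if receptor_positions is None
                 else np.asarray(receptor_positions, dtype=float).reshape(-1, 3))
    rec_world = receptor_transform.apply(rec_model)
    lig_local = grid.positions
    inv_lig = ligand_transform.inverse()
    rec_in_lig = inv_lig.apply(rec_world)

    lig_ghost = ligand.ghost_mask
    rec_ghost = receptor.ghost_mask
    q_l, c6_l, c12_l = ligand.charges, ligand.lj_c6, ligand.lj_c12
    q_r, c6_r, c12_r = receptor.charges, receptor.lj_c6, receptor.lj_c12

    n = rec_world.shape[0]
    forces = np.zeros((n, 3))
    e_rep = e_att = e_el = 0.0
    pair_count = 0
    diel = ff.dielectric

    for i in range(n):
        if rec_ghost[i]:
            continue
        idx = grid.query_within(rec_in_lig[i], ff.cutoff)
        if idx.size:
            idx = idx[~lig_ghost[idx]]
        if idx.size == 0:
            continue
        lig_world = ligand_transform.apply(lig_local[idx])
        dvec = rec_world[i] - lig_world
        r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        r = np.maximum(r, MIN_PAIR_DISTANCE)
        pair_count += idx.size
        c6, c12 = combine_lj(c6_r[i], c12_r[i], c6_l[idx], c12_l[idx],
                             ff.combination_rule)
        inv_r = 1.0 / r
        inv_r6 = inv_r ** 6
        fmag = np.zeros_like(r)
        if ff.vdw_repulsive:
            e_rep += float(np.sum(c12 * inv_r6 * inv_r6))
            fmag += 12.0 * c12 * inv_r6 * inv_r6 * inv_r
        if ff.vdw_attractive:
            e_att += float(np.sum(-c6 * inv_r6))
            fmag += -6.0 * c6 * inv_r6 * inv_r
        if ff.electrostatic:
            qq = COULOMB_CONSTANT * q_r[i] * q_l[idx]
            if diel.kind == "distance_dependent":
                e_el += float(np.sum(qq / (diel.slope * r * r)))
                fmag += 2.0 * qq / (diel.slope * r ** 3)
            else:
                e_el += float(np.sum(qq / (diel.epsilon_r * r)))
                fmag += qq / (diel.epsilon_r * r * r)
        forces[i] = np.sum((fmag * inv_r)[:, None] * dvec, axis=0)

    return ForceReport(
        per_receptor_atom_force=forces,
        total_force_on_receptor=forces.sum(axis=0),
        energy_vdw_repulsive=e_rep,
        energy_vdw_attractive=e_att,
        energy_electrostatic=e_el,
        pair_count=pair_count,
    )
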