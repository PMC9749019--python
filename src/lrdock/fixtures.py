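"""Deterministic synthetic-data generators.

Every generator is a pure function of its arguments and a seed, so all
modules are testable without any external structure files. The random
clouds emulate non-clashing heavy-atom packing (a minimum pair separation,
default 2 A — real nonbonded contacts are never closer); the harmonic
ensembles emulate equilibrium fluctuations with a few planted collective
modes plus isotropic noise, with mode directions orthogonal to the
rigid-body subspace as for physical internal modes.
"""

from __future__ import annotations

import numpy as np

from .chem_io import Atom, Molecule, element_fallback_params
from .errors import ValidationError
from .hbond import HBondCriteria
from .linear_response import ResponseModel
from .nonbonded import DielectricModel, ForceField
from .session import Session
from .transforms import RigidTransform

_ELEMENT_CYCLE = ("C", "N", "O", "C", "S", "C", "O", "N", "P", "C")
_CHARGE_CYCLE = (0.15, -0.15, 0.30, -0.30, 0.0)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _make_atom(i: int, element: str, position, charge: float,
               residue: str = "UNK", chain: str = "A", name: str | None = None) -> Atom:
    c6, c12, radius = element_fallback_params(element)
    if element == "H":
        c6 = c12 = 0.0
    return Atom(serial=i + 1, name=name or f"{element}{i + 1}",
                element=element, residue_name=residue, residue_seq=i + 1,
                chain=chain, position=np.asarray(position, dtype=float),
                charge=charge, lj_c6=c6, lj_c12=c12, vdw_radius=radius,
                is_hydrogen=(element == "H"))


def make_random_cloud(n: int, box: float = 40.0, seed: int = 0,
                      min_separation: float = 2.0,
                      avoid: np.ndarray | None = None,
                      charged: bool = True, chain: str = "A") -> Molecule:
    """n atoms uniform in a cubic box, element-cycled fallback parameters.

    Rejection sampling keeps every pair (and every pair against ``avoid``)
    at least ``min_separation`` apart.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    placed: list[np.ndarray] = []
    blockers = ([] if avoid is None else
                [np.asarray(p, dtype=float) for p in np.atleast_2d(avoid)])
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 20000 * n:
            raise ValidationError("cannot place atoms at this density; "
                                  "increase box or lower min_separation")
        p = rng.uniform(0.0, box, size=3)
        ok = all(np.linalg.norm(p - q) >= min_separation
                 for q in placed + blockers)
        if ok:
            placed.append(p)
    atoms = []
    for i, p in enumerate(placed):
        el = _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)]
        q = _CHARGE_CYCLE[i % len(_CHARGE_CYCLE)] if charged else 0.0
        atoms.append(_make_atom(i, el, p, q, chain=chain))
    mol = Molecule(atoms, title=f"cloud-{n}-{seed}")
    mol.parameters_assigned = True
    return mol


def make_toy_pair(n_receptor: int = 30, n_ligand: int = 10, box: float = 25.0,
                  seed: int = 0, min_separation: float = 2.0):
    """A receptor/ligand pair sharing one box, cross-pairs separated too.

    One combined cloud is generated and split, so intermolecular distances
    obey the same minimum separation as intramolecular ones.
    """
    combined = make_random_cloud(n_receptor + n_ligand, box=box, seed=seed,
                                 min_separation=min_separation)
    rec = Molecule(combined.atoms[:n_receptor], title=f"toy-receptor-{seed}")
    lig_atoms = []
    for i, a in enumerate(combined.atoms[n_receptor:]):
        a.serial = i + 1
        a.chain = "B"
        lig_atoms.append(a)
    lig = Molecule(lig_atoms, title=f"toy-ligand-{seed}")
    rec.parameters_assigned = lig.parameters_assigned = True
    return rec, lig


# ---------------------------------------------------------------------------
# ensembles

def rigid_body_basis(base_positions: np.ndarray) -> np.ndarray:
    """Orthonormal 3N x 6 basis of translations and infinitesimal rotations
    about the centroid."""
    pos = np.asarray(base_positions, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    centered = pos - pos.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        cols.append(t.reshape(-1))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        cols.append(np.cross(np.broadcast_to(e, (n, 3)), centered).reshape(-1))
    B = np.array(cols).T
    Q, _ = np.linalg.qr(B)
    return Q


def make_harmonic_ensemble(n_atoms: int, modes, noise_sd: float = 0.0,
                           n_frames: int = 1000, seed: int = 0,
                           base_positions: np.ndarray | None = None):
    """Gaussian ensemble with planted covariance.

    ``modes`` is a list of (direction, lambda) with lambda in A^2; a
    direction of None draws a random one. Directions are projected out of
    the rigid-body subspace and orthonormalized, then frames are
    base + sum_m sqrt(lambda_m) z_m v_m + noise, z ~ N(0,1). Returns
    (ensemble (F, 3N), info) where info holds the base coordinates and the
    directions actually used.
    """
    rng = _rng(seed)
    if base_positions is None:
        base = make_random_cloud(n_atoms, box=3.0 * max(n_atoms ** (1 / 3), 2.0) * 2.0,
                                 seed=seed).positions
    else:
        base = np.asarray(base_positions, dtype=float).reshape(-1, 3)
    n3 = 3 * base.shape[0]
    rigid = rigid_body_basis(base)
    dirs = []
    lambdas = []
    for direction, lam in modes:
        if lam < 0:
            raise ValidationError("mode variance must be non-negative")
        v = (rng.normal(size=n3) if direction is None
             else np.asarray(direction, dtype=float).reshape(n3).copy())
        v -= rigid @ (rigid.T @ v)
        for u in dirs:
            v -= u * (u @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValidationError("mode direction degenerate after projection")
        dirs.append(v / norm)
        lambdas.append(float(lam))
    flat_base = base.reshape(-1)
    F = int(n_frames)
    frames = np.tile(flat_base, (F, 1))
    for v, lam in zip(dirs, lambdas):
        z = rng.normal(size=F)
        frames += np.sqrt(lam) * z[:, None] * v[None, :]
    if noise_sd > 0:
        frames += rng.normal(scale=noise_sd, size=frames.shape)
    info = {"base": flat_base, "directions": np.array(dirs),
            "lambdas": np.array(lambdas), "noise_sd": float(noise_sd)}
    return frames, info


# ---------------------------------------------------------------------------
# hydrogen-bond geometry

def make_hbond_geometry(d_ha: float, angle_deg: float):
    """Exact (donor molecule, acceptor molecule) with prescribed geometry.

    Donor D at the origin, H 1.0 A along +x; the acceptor is placed in the
    xy-plane so that d(H, A) = d_ha and the D-H...A angle equals
    ``angle_deg`` exactly (180 = linear).
    """
    theta = np.radians(angle_deg)
    h = np.array([1.0, 0.0, 0.0])
    a_pos = h + d_ha * np.array([-np.cos(theta), np.sin(theta), 0.0])
    d_atom = _make_atom(0, "N", [0.0, 0.0, 0.0], 0.0, name="N1")
    h_atom = _make_atom(1, "H", h, 0.0, name="H1")
    d_atom.is_donor = True
    d_atom.bonded_hydrogens = [1]
    donor = Molecule([d_atom, h_atom], title="donor")
    donor.parameters_assigned = True
    a_atom = _make_atom(0, "O", a_pos, 0.0, name="O1")
    a_atom.is_acceptor = True
    acceptor = Molecule([a_atom], title="acceptor")
    acceptor.parameters_assigned = True
    return donor, acceptor


def make_hbond_cloud(n_donors: int, n_acceptors: int, box: float = 15.0,
                     seed: int = 0):
    """Random donor cloud (one hydrogen each, random orientation) plus a
    random acceptor cloud in the same box."""
    rng = _rng(seed)
    donors = []
    idx = 0
    for i in range(n_donors):
        d_pos = rng.uniform(0.0, box, size=3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        d_atom = _make_atom(idx, "N", d_pos, 0.0)
        d_atom.is_donor = True
        d_atom.bonded_hydrogens = [idx + 1]
        h_atom = _make_atom(idx + 1, "H", d_pos + u, 0.0)
        donors.extend([d_atom, h_atom])
        idx += 2
    donor_mol = Molecule(donors, title=f"hb-donors-{seed}")
    donor_mol.parameters_assigned = True
    acceptors = []
    for i in range(n_acceptors):
        a = _make_atom(i, "O", rng.uniform(0.0, box, size=3), 0.0, chain="B")
        a.is_acceptor = True
        acceptors.append(a)
    acc_mol = Molecule(acceptors, title=f"hb-acceptors-{seed}")
    acc_mol.parameters_assigned = True
    return donor_mol, acc_mol


# ---------------------------------------------------------------------------
# salt-bridge scene

def make_salt_bridge_scene(seed: int = 0, temperature: float = 300.0) -> Session:
    """Minimal charged-probe scene for the electrostatics on/off/on
    state machine.

    The receptor holds a +1 donor probe with two hydrogens (one pointing at
    an internal -1 acceptor 3.2 A behind it, one toward the ligand), and a
    single-atom -1 ligand acceptor 3.9 A ahead. A one-mode response model
    lets the probe (and its hydrogens) slide along x. With electrostatics on,
    the ligand's pull relaxes the probe ~1 A forward: the probe-ligand
    hydrogen bond forms and the internal one breaks. Switching
    electrostatics off leaves only a weak vdW attraction, so the probe
    returns to within ~0.05 A of the relaxed structure and the internal
    bond re-forms.
    """
    probe = _make_atom(0, "N", [0.0, 0.0, 0.0], 1.0, residue="PRB", name="NZ")
    h_fwd = _make_atom(1, "H", [1.0, 0.0, 0.0], 0.0, residue="PRB", name="HZ1")
    h_back = _make_atom(2, "H", [-1.0, 0.0, 0.0], 0.0, residue="PRB", name="HZ2")
    internal = _make_atom(3, "O", [-3.2, 0.0, 0.0], -1.0, residue="INT", name="OI")
    probe.lj_c6, probe.lj_c12 = 2262.0, 1.0e6
    internal.lj_c6, internal.lj_c12 = 2262.0, 1.0e6
    probe.is_donor = True
    probe.bonded_hydrogens = [1, 2]
    internal.is_acceptor = True
    receptor = Molecule([probe, h_fwd, h_back, internal], title="salt-bridge-receptor")
    receptor.parameters_assigned = True

    lig_atom = _make_atom(0, "O", [0.0, 0.0, 0.0], -1.0, residue="LIG",
                          name="OL", chain="B")
    lig_atom.lj_c6, lig_atom.lj_c12 = 2262.0, 1.0e6
    lig_atom.is_acceptor = True
    ligand = Molecule([lig_atom], title="salt-bridge-ligand")
    ligand.parameters_assigned = True

    # one mode: probe + both hydrogens slide together along x
    v = np.zeros(12)
    v[0] = v[3] = v[6] = 1.0 / np.sqrt(3.0)
    model = ResponseModel(
        r_o=receptor.positions.reshape(-1), V=v[:, None],
        lambdas=np.array([0.3]),
        beta=ResponseModel.beta_from_temperature(temperature))

    ff = ForceField(dielectric=DielectricModel(kind="distance_dependent",
                                               slope=4.0))
    session = Session(receptor, ligand, force_field=ff,
                      collision_mode="force", collision_threshold=1.0e6,
                      response_model=model, track_hbonds=True,
                      hbond_criteria=HBondCriteria())
    session.ligand_transform = RigidTransform(
        np.eye(3), np.array([3.9, 0.0, 0.0]))
    return session
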