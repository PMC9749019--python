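"""Molecular structure I/O and nonbonded parameter assignment.

Structures are read with gemmi (PDB and mmCIF), flattened to a simple
:class:`Molecule` of :class:`Atom` records (first model only, highest-occupancy
altloc). Nonbonded parameters — partial charge, GROMOS-style C6/C12
Lennard-Jones coefficients and a van der Waals radius — come from an explicit
:class:`ParameterTable` (JSON), never from an external topology generator.
Donor/acceptor roles for hydrogen bonding are flagged during assignment.

Output is fixed-column PDB only, matching the engine's session-export
contract.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .errors import (EmptyStructureError, ParameterLookupError, ShapeError,
                     ValidationError)

logger = logging.getLogger(__name__)

#: Boltzmann constant, kJ mol^-1 K^-1 (GROMACS-compatible energy units).
K_BOLTZMANN = 0.0083144621

#: Covalent X-H association threshold, Angstrom.
COVALENT_H_THRESHOLD = 1.25

#: Element-based fallback vdW radii, Angstrom (Bondi-style).
ELEMENT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

#: Fallback LJ well depth per element, kJ/mol, used with sigma derived from
#: the vdW radius (minimum at the vdW contact distance).
_FALLBACK_EPSILON = {"C": 0.40, "N": 0.50, "O": 0.65, "S": 1.00, "H": 0.10, "P": 0.80}

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


def element_fallback_params(element: str) -> tuple[float, float, float]:
    """(c6, c12, vdw_radius) for an element from the fallback table.

    sigma is chosen so the LJ minimum sits at twice the vdW radius.
    """
    el = element.capitalize()
    radius = ELEMENT_VDW.get(el, 1.70)
    eps = _FALLBACK_EPSILON.get(el, 0.40)
    sigma = 2.0 * radius / _SIXTH_ROOT_2
    c6 = 4.0 * eps * sigma ** 6
    c12 = 4.0 * eps * sigma ** 12
    return c6, c12, radius


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray
    charge: float = 0.0
    lj_c6: float = 0.0
    lj_c12: float = 0.0
    vdw_radius: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False
    is_hydrogen: bool = False
    bonded_hydrogens: list = field(default_factory=list)
    is_ghost: bool = False
    insertion_code: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    het: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


class Molecule:
    """An ordered atom collection with cached per-atom numpy arrays.

    Mutate coordinates only through :meth:`set_positions` so caches stay
    coherent.
    """

    def __init__(self, atoms, title: str = "", source_format: str | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        self.source_format = source_format
        self.parameters_assigned = False
        self.conect: dict[int, set[int]] = {}
        self.unbonded_hydrogens: list[int] = []
        self._cache: dict = {}

    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i):
        return self.atoms[i]

    def _invalidate(self):
        self._cache.clear()

    def _cached(self, key, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]

    @property
    def positions(self) -> np.ndarray:
        return self._cached("pos", lambda: np.array([a.position for a in self.atoms], dtype=float))

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float).reshape(len(self.atoms), 3)
        if not np.all(np.isfinite(pos)):
            raise ValidationError("non-finite coordinates")
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()
        self._invalidate()

    @property
    def charges(self) -> np.ndarray:
        return self._cached("q", lambda: np.array([a.charge for a in self.atoms], dtype=float))

    @property
    def lj_c6(self) -> np.ndarray:
        return self._cached("c6", lambda: np.array([a.lj_c6 for a in self.atoms], dtype=float))

    @property
    def lj_c12(self) -> np.ndarray:
        return self._cached("c12", lambda: np.array([a.lj_c12 for a in self.atoms], dtype=float))

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._cached("rvdw", lambda: np.array([a.vdw_radius for a in self.atoms], dtype=float))

    @property
    def ghost_mask(self) -> np.ndarray:
        return np.array([a.is_ghost for a in self.atoms], dtype=bool)

    @property
    def hydrogen_mask(self) -> np.ndarray:
        return self._cached("hmask", lambda: np.array([a.is_hydrogen for a in self.atoms], dtype=bool))

    @property
    def donor_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_donor], dtype=int)

    @property
    def acceptor_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_acceptor], dtype=int)

    def set_ghost(self, indices, ghost: bool = True) -> None:
        for i in np.atleast_1d(np.asarray(indices, dtype=int)):
            self.atoms[int(i)].is_ghost = ghost
        self._invalidate()

    def copy(self) -> "Molecule":
        import copy as _copy
        m = Molecule([_copy.deepcopy(a) for a in self.atoms], title=self.title,
                     source_format=self.source_format)
        m.parameters_assigned = self.parameters_assigned
        m.conect = {k: set(v) for k, v in self.conect.items()}
        m.unbonded_hydrogens = list(self.unbonded_hydrogens)
        return m


# ---------------------------------------------------------------------------
# structure reading

_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _parse_conect(path: Path) -> dict[int, set[int]]:
    bonds: dict[int, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = [line[i:i + 5].strip() for i in range(6, 31, 5)]
            nums = [int(f) for f in fields if f]
            if len(nums) < 2:
                continue
            a = nums[0]
            for b in nums[1:]:
                bonds.setdefault(a, set()).add(b)
                bonds.setdefault(b, set()).add(a)
    return bonds


def read_structure(path, format: str = "auto") -> Molecule:
    """Read a PDB or mmCIF file into a :class:`Molecule`.

    First model only; for alternate locations the highest-occupancy conformer
    is kept (ties broken by file order). Chemistry fields stay unassigned
    until :func:`assign_parameters`.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise ValidationError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            best: dict[str, tuple[float, int]] = {}  # name -> (occ, index into atoms)
            for at in res:
                key = at.name
                if key in best:
                    occ_prev, idx = best[key]
                    if at.occ > occ_prev:
                        old = atoms[idx]
                        atoms[idx] = _gemmi_atom(at, res, chain, old.serial)
                        best[key] = (at.occ, idx)
                    continue
                atoms.append(_gemmi_atom(at, res, chain, None))
                best[key] = (at.occ, len(atoms) - 1)
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    if not np.all(np.isfinite(np.array([a.position for a in atoms]))):
        raise ValidationError(f"{path}: non-finite coordinates")
    mol = Molecule(atoms, title=st.name or path.stem, source_format=_detect_format(path, format))
    if mol.source_format == "pdb":
        mol.conect = _parse_conect(path)
    return mol


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    return "mmcif" if suffix in (".cif", ".mmcif") else "pdb"


def _gemmi_atom(at: gemmi.Atom, res, chain, serial_override) -> Atom:
    element = at.element.name if at.element else ""
    return Atom(
        serial=serial_override if serial_override is not None else at.serial,
        name=at.name,
        element=element,
        residue_name=res.name,
        residue_seq=res.seqid.num,
        chain=chain.name,
        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
        is_hydrogen=element in ("H", "D"),
        insertion_code=(res.seqid.icode or "").strip(),
        altloc=at.altloc or "",
        occupancy=at.occ,
        het=res.het_flag == "H",
    )


# ---------------------------------------------------------------------------
# PDB writing

def _pdb_atom_name(name: str, element: str) -> str:
    # Standard PDB convention: 1-2 letter elements start in column 14 unless
    # the name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(molecule: Molecule, path) -> None:
    """Write fixed-column PDB ATOM/HETATM records, TER between chains, END."""
    if len(molecule) == 0:
        raise EmptyStructureError("refusing to write an empty molecule")
    lines = []
    prev_chain = None
    last = None
    for a in molecule.atoms:
        if prev_chain is not None and a.chain != prev_chain:
            lines.append(_ter_line(last))
        rec = "HETATM" if a.het else "ATOM  "
        name = _pdb_atom_name(a.name, a.element)
        x, y, z = a.position
        lines.append(
            f"{rec}{a.serial:>5d} {name}{'':1s}{a.residue_name:<3s} {a.chain[:1]:1s}"
            f"{a.residue_seq:>4d}{a.insertion_code[:1]:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
        prev_chain = a.chain
        last = a
    lines.append(_ter_line(last))
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _ter_line(a: Atom) -> str:
    return (f"TER   {a.serial + 1:>5d}      {a.residue_name:<3s} {a.chain[:1]:1s}"
            f"{a.residue_seq:>4d}")


# ---------------------------------------------------------------------------
# parameter tables

@dataclass
class ParameterEntry:
    charge: float = 0.0
    c6: float = 0.0
    c12: float = 0.0
    vdw_radius: float = 0.0
    role: str | None = None  # "donor" | "acceptor" | "both" | None


class ParameterTable:
    """Per-(residue, atom) nonbonded parameters plus donor/acceptor roles.

    JSON layout::

        {"combination_rule": "geometric",
         "provenance": "...",
         "entries": {"HOH": {"O": {"charge": -0.82, "c6": ..., "c12": ...,
                                   "vdw_radius": 1.52, "role": "both"}}}}

    Entries may give ``sigma``/``epsilon`` (Angstrom, kJ/mol) instead of
    ``c6``/``c12``; they are converted via c6 = 4 eps sigma^6,
    c12 = 4 eps sigma^12. A missing vdW radius defaults to sigma·2^(1/6)/2.
    """

    def __init__(self, entries: dict, combination_rule: str = "geometric",
                 provenance: str = ""):
        if combination_rule not in ("geometric", "lorentz_berthelot"):
            raise ValidationError(f"unknown combination rule {combination_rule!r}")
        self.combination_rule = combination_rule
        self.provenance = provenance
        self._entries: dict[tuple[str, str], ParameterEntry] = {}
        for res_name, atoms in entries.items():
            for atom_name, raw in atoms.items():
                self._entries[(res_name, atom_name)] = self._build_entry(raw)

    @staticmethod
    def _build_entry(raw: dict) -> ParameterEntry:
        if "sigma" in raw or "epsilon" in raw:
            sigma = float(raw.get("sigma", 0.0))
            eps = float(raw.get("epsilon", 0.0))
            c6 = 4.0 * eps * sigma ** 6
            c12 = 4.0 * eps * sigma ** 12
        else:
            c6 = float(raw.get("c6", 0.0))
            c12 = float(raw.get("c12", 0.0))
            sigma = (c12 / c6) ** (1.0 / 6.0) if c6 > 0 and c12 > 0 else 0.0
        radius = float(raw.get("vdw_radius", 0.0))
        if radius <= 0.0:
            radius = sigma * _SIXTH_ROOT_2 / 2.0 if sigma > 0 else 1.5
        entry = ParameterEntry(charge=float(raw.get("charge", 0.0)), c6=c6, c12=c12,
                               vdw_radius=radius, role=raw.get("role"))
        if entry.c6 < 0 or entry.c12 < 0 or entry.vdw_radius <= 0:
            raise ValidationError("invalid LJ parameters in table entry")
        return entry

    def lookup(self, residue_name: str, atom_name: str) -> ParameterEntry | None:
        e = self._entries.get((residue_name, atom_name))
        if e is None:
            e = self._entries.get(("*", atom_name))
        return e

    @classmethod
    def from_json(cls, source) -> "ParameterTable":
        if isinstance(source, (str, Path)):
            data = json.loads(Path(source).read_text())
        else:
            data = source
        return cls(data.get("entries", {}),
                   combination_rule=data.get("combination_rule", "geometric"),
                   provenance=data.get("provenance", ""))

    @classmethod
    def bundled(cls) -> "ParameterTable":
        """The mini table shipped with the package (fixture chemistry only)."""
        text = resources.files("lrdock.data").joinpath("mini_params.json").read_text()
        return cls.from_json(json.loads(text))


def load_donor_acceptor_map(source=None) -> dict:
    """residue -> atom name -> role map; bundled default covers standard
    amino acids, nucleotides, water and common ligand atom names."""
    if source is None:
        text = resources.files("lrdock.data").joinpath("donor_acceptor.json").read_text()
        return json.loads(text)
    if isinstance(source, (str, Path)):
        return json.loads(Path(source).read_text())
    return dict(source)


# ---------------------------------------------------------------------------
# parameter assignment

def associate_hydrogens(molecule: Molecule) -> dict[int, list[int]]:
    """Map heavy-atom index -> bonded hydrogen indices.

    A hydrogen bonds to the nearest heavy atom within 1.25 Angstrom; CONECT
    records, when present, override the distance rule. Orphan hydrogens are
    logged and listed in ``molecule.unbonded_hydrogens``, never dropped.
    """
    pos = molecule.positions
    h_idx = np.where(molecule.hydrogen_mask)[0]
    heavy_idx = np.where(~molecule.hydrogen_mask)[0]
    serial_to_index = {a.serial: i for i, a in enumerate(molecule.atoms)}
    bonded: dict[int, list[int]] = {}
    orphans: list[int] = []
    heavy_pos = pos[heavy_idx] if len(heavy_idx) else np.zeros((0, 3))
    for h in h_idx:
        parent = None
        for nb_serial in molecule.conect.get(molecule.atoms[h].serial, ()):
            j = serial_to_index.get(nb_serial)
            if j is not None and not molecule.atoms[j].is_hydrogen:
                parent = j
                break
        if parent is None and len(heavy_idx):
            d = np.linalg.norm(heavy_pos - pos[h], axis=1)
            k = int(np.argmin(d))
            if d[k] < COVALENT_H_THRESHOLD:
                parent = int(heavy_idx[k])
        if parent is None:
            orphans.append(int(h))
        else:
            bonded.setdefault(parent, []).append(int(h))
    if orphans:
        logger.warning("hydrogens with no heavy atom within %.2f A: %s",
                       COVALENT_H_THRESHOLD, orphans)
    molecule.unbonded_hydrogens = orphans
    return bonded


def assign_parameters(molecule: Molecule, table: ParameterTable | None = None,
                      policy: str = "strict",
                      donor_acceptor_map: dict | None = None) -> Molecule:
    """Assign charge, C6/C12, vdW radius and donor/acceptor roles in place.

    policy "strict" raises :class:`ParameterLookupError` listing every unknown
    (residue, atom); "lenient" falls back to element-based vdW radii with zero
    charge and element-default C6/C12, logging a warning per atom.
    """
    if policy not in ("strict", "lenient"):
        raise ValidationError(f"unknown policy {policy!r}")
    if table is None:
        table = ParameterTable.bundled()
    da_map = donor_acceptor_map
    bonded = associate_hydrogens(molecule)
    missing: list[tuple[str, str]] = []
    fallbacks: list[str] = []
    for a in molecule.atoms:
        entry = table.lookup(a.residue_name, a.name)
        if entry is None:
            if policy == "strict":
                missing.append((a.residue_name, a.name))
                continue
            c6, c12, radius = element_fallback_params(a.element or a.name[:1])
            if a.is_hydrogen:
                c6 = c12 = 0.0
            a.charge, a.lj_c6, a.lj_c12, a.vdw_radius = 0.0, c6, c12, radius
            role = None
            fallbacks.append(f"{a.residue_name}/{a.name}")
        else:
            a.charge, a.lj_c6, a.lj_c12 = entry.charge, entry.c6, entry.c12
            a.vdw_radius = entry.vdw_radius
            role = entry.role
        if da_map is not None:
            res_map = da_map.get(a.residue_name, da_map.get("*", {}))
            role = res_map.get(a.name, role)
        a.is_acceptor = role in ("acceptor", "both") and not a.is_hydrogen
        a.is_donor = False
        a.bonded_hydrogens = []
    if missing:
        raise ParameterLookupError(sorted(set(missing)))
    if fallbacks:
        logger.warning("element fallback used for %d atoms (%s%s)",
                       len(fallbacks), ", ".join(fallbacks[:5]),
                       ", ..." if len(fallbacks) > 5 else "")
    role_of: dict[int, str | None] = {}
    for i, a in enumerate(molecule.atoms):
        entry = table.lookup(a.residue_name, a.name)
        role = entry.role if entry else None
        if da_map is not None:
            res_map = da_map.get(a.residue_name, da_map.get("*", {}))
            role = res_map.get(a.name, role)
        role_of[i] = role
    for heavy, hs in bonded.items():
        if role_of.get(heavy) in ("donor", "both"):
            molecule.atoms[heavy].is_donor = True
            molecule.atoms[heavy].bonded_hydrogens = sorted(hs)
    molecule.parameters_assigned = True
    molecule._invalidate()
    return molecule


# ---------------------------------------------------------------------------
# response-model files

def write_response_model(model, eigenvalues_path, eigenvectors_path) -> None:
    """Plain-text model files: one eigenvalue (A^2) per line, descending;
    eigenvector file has M rows of 3N whitespace-separated components."""
    np.savetxt(eigenvalues_path, model.lambdas, fmt="%.17g")
    np.savetxt(eigenvectors_path, model.V.T, fmt="%.17g")


def read_response_model(eigenvalues_path, eigenvectors_path, relaxed_structure,
                        temperature: float = 300.0):
    """Load eigenvalue/eigenvector files against a relaxed structure.

    ``relaxed_structure`` may be a Molecule or a flat 3N coordinate array.
    beta is set to 1/(k_b T) in mol/kJ.
    """
    from .linear_response import ResponseModel  # local import, avoids cycle

    if isinstance(relaxed_structure, Molecule):
        r_o = relaxed_structure.positions.reshape(-1)
    else:
        r_o = np.asarray(relaxed_structure, dtype=float).reshape(-1)
    lambdas = np.atleast_1d(np.loadtxt(eigenvalues_path, dtype=float))
    if np.any(lambdas < 0):
        raise ValidationError("negative eigenvalue in model file")
    with open(eigenvectors_path) as fh:
        rows = [np.array(line.split(), dtype=float)
                for line in fh if line.strip()]
    if len(rows) != len(lambdas):
        raise ShapeError(f"{len(lambdas)} eigenvalues but {len(rows)} eigenvector rows")
    n3 = r_o.size
    for m, row in enumerate(rows):
        if row.size != n3:
            raise ShapeError(f"eigenvector row {m} has length {row.size}, expected {n3}")
    V = np.array(rows).T  # 3N x M
    beta = 1.0 / (K_BOLTZMANN * temperature)
    return ResponseModel(r_o=r_o, V=V, lambdas=lambdas, beta=beta)


# ---------------------------------------------------------------------------
# coordinate ensembles

def read_ensemble(path) -> np.ndarray:
    """Read an (F, 3N) coordinate ensemble.

    Multi-MODEL PDB/mmCIF files are read with gemmi; anything else is parsed
    as a plain text file with one frame of 3N whitespace-separated values per
    non-empty line.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif"):
        st = gemmi.read_structure(str(path))
        frames = []
        for model in st:
            coords = [[at.pos.x, at.pos.y, at.pos.z]
                      for chain in model for res in chain for at in res]
            frames.append(np.array(coords, dtype=float).reshape(-1))
        if not frames:
            raise EmptyStructureError(f"{path}: no models")
        arr = np.array(frames)
    else:
        arr = np.atleast_2d(np.loadtxt(path, dtype=float))
    if arr.shape[1] % 3 != 0:
        raise ShapeError("frame length is not a multiple of 3")
    return arr


def write_ensemble(ensemble: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(ensemble, dtype=float), fmt="%.10g")
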