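import numpy as np
import pytest

from lrdock.fixtures import make_random_cloud, make_toy_pair


@pytest.fixture
def toy_pair():
    return make_toy_pair(n_receptor=30, n_ligand=10, box=25.0, seed=1)


@pytest.fixture
def cloud50():
    return make_random_cloud(50, box=30.0, seed=2)


WATER_PDB = """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.930   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_PDB)
    return p


# ---------------------------------------------------------------------------
# independent oracles shared by unit and acceptance tests; deliberately
# written as plain double/triple loops, no lrdock grid machinery

K_E = 1389.35458


def brute_force_report(rec, lig, cutoff=8.0, diel_slope=4.0,
                       components=(True, True, True),
                       lig_transform=None, rec_positions=None):
    """O(N*M) double-loop force/energy oracle (geometric combination)."""
    rep_on, att_on, el_on = components
    rpos = rec.positions if rec_positions is None else np.asarray(rec_positions)
    lpos = lig.positions
    if lig_transform is not None:
        lpos = lpos @ lig_transform.rotation.T + lig_transform.translation
    n, m = len(rpos), len(lpos)
    F = np.zeros((n, 3))
    e_rep = e_att = e_el = 0.0
    pairs = 0
    for i in range(n):
        if rec.atoms[i].is_ghost:
            continue
        for j in range(m):
            if lig.atoms[j].is_ghost:
                continue
            d = rpos[i] - lpos[j]
            r = np.sqrt(d @ d)
            if r >= cutoff:
                continue
            pairs += 1
            fmag = 0.0
            c6 = np.sqrt(rec.lj_c6[i] * lig.lj_c6[j])
            c12 = np.sqrt(rec.lj_c12[i] * lig.lj_c12[j])
            if rep_on:
                e_rep += c12 / r ** 12
                fmag += 12 * c12 / r ** 13
            if att_on:
                e_att += -c6 / r ** 6
                fmag += -6 * c6 / r ** 7
            if el_on:
                qq = K_E * rec.charges[i] * lig.charges[j]
                e_el += qq / (diel_slope * r * r)
                fmag += 2 * qq / (diel_slope * r ** 3)
            F[i] += fmag * d / r
    return F, (e_rep, e_att, e_el), pairs


def brute_hbonds(donor_mol, acceptor_mol, dist_cut=2.5, angle_cut=90.0,
                 don_transform=None, acc_transform=None):
    """Exhaustive (donor, hydrogen, acceptor) triple loop."""
    dpos = donor_mol.positions
    if don_transform is not None:
        dpos = dpos @ don_transform.rotation.T + don_transform.translation
    apos = acceptor_mol.positions
    if acc_transform is not None:
        apos = apos @ acc_transform.rotation.T + acc_transform.translation
    out = set()
    same = donor_mol is acceptor_mol
    for d, atom in enumerate(donor_mol.atoms):
        if not atom.is_donor:
            continue
        for h in atom.bonded_hydrogens:
            for a, acc in enumerate(acceptor_mol.atoms):
                if not acc.is_acceptor:
                    continue
                if same and (a == d or a == h or a in atom.bonded_hydrogens):
                    continue
                v_ha = apos[a] - dpos[h]
                dist = np.linalg.norm(v_ha)
                if dist >= dist_cut:
                    continue
                v_hd = dpos[d] - dpos[h]
                c = np.clip(v_hd @ v_ha / (np.linalg.norm(v_hd) * dist), -1, 1)
                angle = np.degrees(np.arccos(c))
                if angle > angle_cut:
                    out.add((d, a, h))
    return out


def brute_max_penetration(rec, lig, cutoff=8.0, lig_transform=None):
    lpos = lig.positions
    if lig_transform is not None:
        lpos = lpos @ lig_transform.rotation.T + lig_transform.translation
    best = 0.0
    for i in range(len(rec)):
        for j in range(len(lig)):
            d = np.linalg.norm(rec.positions[i] - lpos[j])
            if d >= cutoff:
                continue
            best = max(best, rec.vdw_radii[i] + lig.vdw_radii[j] - d)
    return best
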