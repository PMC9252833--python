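"""Shared builders: synthetic residues/chains and parsed fixture structures."""

from __future__ import annotations

import numpy as np
import pytest

from molcontact import Chain, classify_chain, make_fixture, parse_pdb
from molcontact.structure import Atom, Residue, residue_kind


def make_residue(name, chain_id="A", seq=1, icode="", atoms=None, element_map=None):
    """Build a Residue from {atom_name: (x, y, z)}; elements inferred from names."""
    atom_objs = []
    for aname, xyz in (atoms or {}).items():
        if element_map and aname in element_map:
            elem = element_map[aname]
        else:
            elem = aname.strip("0123456789'")[0]
        atom_objs.append(Atom(aname, elem, np.asarray(xyz, dtype=float)))
    return Residue(chain_id, seq, icode, name, atom_objs, residue_kind(name))


def make_chain(residues, chain_id="A"):
    ch = Chain(chain_id, list(residues))
    ch.polymer_type = classify_chain(ch)
    return ch


def random_chain(n_res, seed, chain_id="A", atoms_per_res=4, spread=3.0):
    """Random-coil chain: residues strung along x with jittered atoms."""
    rng = np.random.default_rng(seed)
    names = ["GLY", "ALA", "SER", "LEU", "VAL"]
    residues = []
    for i in range(n_res):
        base = np.array([spread * i, 0.0, 0.0])
        atoms = {}
        for j in range(atoms_per_res):
            atoms[f"C{j + 1}" if j else "CA"] = base + rng.normal(0, 1.2, 3)
        residues.append(make_residue(names[i % len(names)], chain_id, i + 1, atoms=atoms))
    return make_chain(residues, chain_id)


def brute_force_min_dist(res_a, res_b):
    """Independent exhaustive all-pairs heavy-atom minimum distance."""
    best = np.inf
    for a in res_a.atoms:
        if a.element in ("H", "D"):
            continue
        for b in res_b.atoms:
            if b.element in ("H", "D"):
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            best = min(best, d)
    return best


def random_rotation(seed):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def rigid_transform_chain(chain, rotation, translation):
    moved = chain.copy()
    for res in moved.residues:
        for a in res.atoms:
            a.coords = rotation @ a.coords + np.asarray(translation, dtype=float)
    return moved


@pytest.fixture
def salt_bridge_chains():
    st = parse_pdb(make_fixture("salt_bridge"))
    return st.model()


@pytest.fixture
def helix_chain():
    st = parse_pdb(make_fixture("helix", n=12))
    return st.model()[0]


@pytest.fixture
def ring_structure():
    return parse_pdb(make_fixture("ring_assembly", k=11))
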