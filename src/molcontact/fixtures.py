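"""Synthetic PDB fixtures with known geometry.

Every other module is testable without downloading anything: this module
writes small, syntactically valid PDB texts whose geometric properties
(distances, stacking angles, hydrogen-bond patterns, ring-assembly
topology) are embedded by construction.  Peptide fixtures are built from
ideal internal coordinates (bond lengths/angles + phi/psi torsions); the
interaction fixtures place the relevant functional groups directly at the
advertised geometry.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np

__all__ = ["make_fixture", "FIXTURE_KINDS", "place_atom", "build_backbone"]


# ---------------------------------------------------------------------------
# PDB text assembly

def _pdb_line(serial: int, name: str, resname: str, chain: str, resnum: int,
              xyz, element: str, altloc: str = "", occ: float = 1.0,
              record: str = "ATOM") -> str:
    disp = name if len(name) == 4 or len(element) > 1 else f" {name}"
    x, y, z = xyz
    return (f"{record:<6s}{serial:5d} {disp:<4s}{altloc or ' '}{resname:>3s} "
            f"{chain}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


class _PdbBuilder:
    def __init__(self) -> None:
        self.lines: list[str] = []
        self.serial = 1

    def remark(self, text: str) -> None:
        self.lines.append(f"REMARK 999 {text}")

    def raw(self, line: str) -> None:
        self.lines.append(line)

    def atom(self, name: str, resname: str, chain: str, resnum: int, xyz,
             element: Optional[str] = None, **kw) -> None:
        if element is None:
            element = name.strip("0123456789'")[0]
        self.lines.append(_pdb_line(self.serial, name, resname, chain, resnum,
                                    xyz, element, **kw))
        self.serial += 1

    def residue(self, resname: str, chain: str, resnum: int,
                atoms: dict[str, tuple]) -> None:
        for name, xyz in atoms.items():
            self.atom(name, resname, chain, resnum, xyz)

    def ter(self) -> None:
        self.lines.append("TER")

    def text(self) -> str:
        return "\n".join(self.lines + ["END"]) + "\n"


# ---------------------------------------------------------------------------
# Internal-coordinate backbone builder

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates.

    ``bond`` = |c-d|, ``angle_deg`` = angle(b, c, d), ``torsion_deg`` =
    dihedral(a, b, c, d).  Standard natural-extension-of-reference-frame
    construction.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal backbone geometry (lengths in Angstroms, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.6, 121.7, 120.8


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) coordinates for a chain of given phi/psi.

    The first residue's phi and the last residue's psi are unused (chain
    termini); omega is fixed at 180 degrees (trans).
    """
    n_res = len(phi_psi)
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0]) * -1
    # orient first C via simple rotation in the xy-plane
    C = np.array([CA[0] - _B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        prev = res[-1]
        Nn = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CAn = place_atom(prev["CA"], prev["C"], Nn, _B_N_CA, _A_C_N_CA, 180.0)
        Cn = place_atom(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl oxygens: O(i) from psi(i) (anti to the next N)
    for i in range(n_res):
        psi = phi_psi[i][1]
        r = res[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


# ---------------------------------------------------------------------------
# Fixture kinds

def _dipeptide_at_distance(d: float = 5.5, **_) -> str:
    b = _PdbBuilder()
    b.remark(f"dipeptide with min heavy-atom distance {d:.3f} A")
    b.residue("GLY", "A", 1, {
        "N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (-0.55, 1.42, 0.0), "O": (-0.2, 2.5, 0.45),
    })
    b.residue("GLY", "A", 2, {
        "CA": (d, 0.0, 0.0), "N": (d + 1.458, 0.0, 0.0),
        "C": (d + 0.55, -1.42, 0.0), "O": (d + 0.2, -2.5, -0.45),
    })
    b.ter()
    return b.text()


def _salt_bridge(**_) -> str:
    """Arg guanidinium facing an Asp carboxylate: NH1...OD1 = 2.80 A."""
    b = _PdbBuilder()
    b.remark("Arg(A) - Asp(B) salt bridge, NH1-OD1 2.80 A, bidentate")
    b.residue("ASP", "B", 1, {
        "N": (-3.3, 1.0, 0.3), "CA": (-2.0, 1.2, 0.3), "C": (-1.8, 2.7, 0.1),
        "O": (-0.9, 3.2, -0.6), "CB": (-1.52, 0.0, 0.0),
        "CG": (0.0, 0.0, 0.0), "OD1": (0.63, 1.08, 0.0), "OD2": (0.63, -1.08, 0.0),
    })
    b.ter()
    b.residue("ARG", "A", 1, {
        "NH1": (3.43, 1.08, 0.0), "NH2": (3.43, -1.08, 0.0),
        "CZ": (4.06, 0.0, 0.0), "NE": (5.39, 0.0, 0.0),
        "CD": (6.2, 1.0, 0.4), "CG": (7.6, 0.8, 0.4), "CB": (8.3, 2.1, 0.6),
        "CA": (9.7, 1.9, 0.7), "N": (10.3, 0.7, 0.8),
        "C": (10.4, 3.2, 0.8), "O": (11.5, 3.3, 1.2),
    })
    b.ter()
    return b.text()


def _hexagon(center: np.ndarray, radius: float = 1.39,
             rot: Optional[np.ndarray] = None) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        a = math.radians(60 * k + 180)  # CG at angle 180 (toward -x)
        p = np.array([radius * math.cos(a), radius * math.sin(a), 0.0])
        if rot is not None:
            p = rot @ p
        pts.append(center + p)
    return pts


_PHE_RING_ORDER = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _phe_residue(b: _PdbBuilder, chain: str, resnum: int, center: np.ndarray,
                 rot: Optional[np.ndarray] = None) -> None:
    ring = _hexagon(center, rot=rot)
    atoms = {name: tuple(p) for name, p in zip(_PHE_RING_ORDER, ring)}
    out = np.array([-1.0, 0.0, 0.0]) if rot is None else rot @ np.array([-1.0, 0.0, 0.0])
    cb = ring[0] + 1.52 * out
    ca = cb + np.array([-0.8, 1.2, 0.3])
    atoms["CB"] = tuple(cb)
    atoms["CA"] = tuple(ca)
    atoms["N"] = tuple(ca + np.array([-1.3, 0.5, 0.2]))
    atoms["C"] = tuple(ca + np.array([-0.3, 1.45, -0.2]))
    atoms["O"] = tuple(ca + np.array([-0.3, 2.4, 0.0]))
    b.residue("PHE", chain, resnum, atoms)


def _aromatic_stack(orientation: str = "parallel", **_) -> str:
    b = _PdbBuilder()
    b.remark(f"two Phe rings, {orientation} stack")
    _phe_residue(b, "A", 1, np.array([0.0, 0.0, 0.0]))
    b.ter()
    if orientation == "parallel":
        # coplanar normals, centroids 3.8 A apart along the shared normal
        _phe_residue(b, "B", 1, np.array([0.0, 0.0, 3.8]))
    elif orientation == "tshaped":
        rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])  # 90 deg about x
        _phe_residue(b, "B", 1, np.array([0.0, 0.0, 4.8]), rot=rot)
    else:
        raise ValueError(f"unknown stack orientation {orientation!r}")
    b.ter()
    return b.text()


def _cation_pi(axial: bool = True, **_) -> str:
    b = _PdbBuilder()
    b.remark(f"Lys NZ {'4.0 A along the Phe ring normal' if axial else '4.0 A in the ring plane'}")
    _phe_residue(b, "A", 1, np.array([0.0, 0.0, 0.0]))
    b.ter()
    nz = np.array([0.0, 0.0, 4.0]) if axial else np.array([4.0, 0.0, 0.0])
    away = np.array([0.0, 0.0, 1.5]) if axial else np.array([1.5, 0.0, 0.0])
    ce = nz + away
    cd = ce + away
    cg = cd + away + np.array([0.0, 1.0, 0.0])
    cb = cg + away
    ca = cb + away + np.array([0.0, 1.0, 0.0])
    b.residue("LYS", "B", 1, {
        "NZ": tuple(nz), "CE": tuple(ce), "CD": tuple(cd), "CG": tuple(cg),
        "CB": tuple(cb), "CA": tuple(ca),
        "N": tuple(ca + np.array([1.2, 0.6, 0.3])),
        "C": tuple(ca + np.array([-0.4, 1.4, 0.2])),
        "O": tuple(ca + np.array([-0.4, 2.4, 0.9])),
    })
    b.ter()
    return b.text()


def _helix(n: int = 12, **_) -> str:
    """Ideal alpha-helix (phi = -57, psi = -47), glycine backbone."""
    bb = build_backbone([(-57.0, -47.0)] * int(n))
    b = _PdbBuilder()
    b.remark(f"ideal alpha-helix, {n} residues, phi=-57 psi=-47")
    for i, r in enumerate(bb, start=1):
        b.residue("GLY", "A", i, {k: tuple(v) for k, v in r.items()})
    b.ter()
    return b.text()


def _sheet_pair(n: int = 8, **_) -> str:
    """Antiparallel two-strand sheet with designed inter-strand O...N = 2.77 A."""
    b = _PdbBuilder()
    b.remark(f"antiparallel beta-sheet pair, {n} residues per strand")
    for i in range(int(n)):
        x = 3.3 * i
        b.residue("GLY", "A", i + 1, {
            "N": (x, 0.0, 0.0), "CA": (x + 1.2, 0.8, 0.5),
            "C": (x + 2.2, 0.0, 0.0), "O": (x + 2.2, -1.23, 0.0),
        })
    b.ter()
    for j in range(int(n)):
        x = 3.3 * j
        b.residue("GLY", "B", j + 1, {
            "N": (x + 2.2, -4.0, 0.0), "CA": (x + 1.2, -4.8, 0.5),
            "C": (x, -4.0, 0.0), "O": (x, -2.77, 0.0),
        })
    b.ter()
    return b.text()


def _extended_strand(n: int = 8, **_) -> str:
    """Single fully extended strand (no partner): all coil by construction."""
    bb = build_backbone([(-139.0, 135.0)] * int(n))
    b = _PdbBuilder()
    b.remark(f"single extended strand, {n} residues")
    for i, r in enumerate(bb, start=1):
        b.residue("GLY", "A", i, {k: tuple(v) for k, v in r.items()})
    b.ter()
    return b.text()


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQSTUVWXYZ"  # 'R' reserved for the nucleic strand


def _ring_assembly(k: int = 11, with_strand: bool = True, **_) -> str:
    """k protein chains on a circle plus one RNA strand threading the inside.

    Adjacent protein chains share 3 residue contacts below 5 A; each protein
    chain has exactly one RNA residue within 5 A.  Non-adjacent chains are
    farther than 5 A apart everywhere.
    """
    if not 3 <= k <= len(_CHAIN_IDS):
        raise ValueError(f"ring size must be in [3, {len(_CHAIN_IDS)}], got {k}")
    R, r_in = 10.0, 6.0
    step = 2.0 * math.pi / k
    gap = 3.5 / R  # chord of ~3.5 A between adjacent interface residues
    delta = (step - gap) / 2.0
    b = _PdbBuilder()
    b.remark(f"{k}-chain protein ring" + (" + RNA strand" if with_strand else ""))
    for m in range(k):
        cid = _CHAIN_IDS[m]
        theta = m * step
        for rn, ang in enumerate((theta - delta, theta, theta + delta), start=1):
            b.residue("GLY", cid, rn, {
                "CA": (R * math.cos(ang), R * math.sin(ang), 0.0),
            })
        b.ter()
    if with_strand:
        for m in range(k):
            theta = m * step
            b.residue("A", "R", m + 1, {
                "C1'": (r_in * math.cos(theta), r_in * math.sin(theta), 0.0),
            })
        b.ter()
    return b.text()


def _multimodel(**_) -> str:
    """Two models of one dipeptide differing by a rigid translation."""
    shift = np.array([10.0, -3.0, 7.0])
    res1 = {"N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
            "C": (-0.55, 1.42, 0.0), "O": (-0.2, 2.5, 0.45)}
    res2 = {"CA": (4.0, 0.0, 0.0), "N": (5.458, 0.0, 0.0),
            "C": (4.55, -1.42, 0.0), "O": (4.2, -2.5, -0.45)}
    b = _PdbBuilder()
    b.remark("two models related by a rigid shift")
    for mi in range(2):
        off = shift * mi
        b.raw(f"MODEL     {mi + 1:4d}")
        b.residue("GLY", "A", 1, {k: tuple(np.array(v) + off) for k, v in res1.items()})
        b.residue("GLY", "A", 2, {k: tuple(np.array(v) + off) for k, v in res2.items()})
        b.ter()
        b.raw("ENDMDL")
    return b.text()


def _biomt_assembly(k: int = 11, **_) -> str:
    """One chain plus REMARK 350 BIOMT operators for k-fold rotation about z."""
    b = _PdbBuilder()
    b.raw("REMARK 350 BIOMOLECULE: 1")
    b.raw("REMARK 350 APPLY THE FOLLOWING TO CHAINS: A")
    for m in range(int(k)):
        ang = 2.0 * math.pi * m / k
        c, s = math.cos(ang), math.sin(ang)
        rows = [(c, -s, 0.0, 0.0), (s, c, 0.0, 0.0), (0.0, 0.0, 1.0, 0.0)]
        for ri, (r1, r2, r3, t) in enumerate(rows, start=1):
            b.raw(f"REMARK 350   BIOMT{ri} {m + 1:3d}{r1:10.6f}{r2:10.6f}{r3:10.6f}"
                  f"{t:15.5f}")
    b.residue("GLY", "A", 1, {
        "N": (8.542, 0.0, 0.0), "CA": (10.0, 0.0, 0.0),
        "C": (10.55, 1.42, 0.0), "O": (10.2, 2.5, 0.45),
    })
    b.ter()
    return b.text()


_GENERATORS: dict[str, Callable[..., str]] = {
    "dipeptide_at_distance": _dipeptide_at_distance,
    "salt_bridge": _salt_bridge,
    "aromatic_stack": _aromatic_stack,
    "cation_pi": _cation_pi,
    "helix": _helix,
    "sheet_pair": _sheet_pair,
    "extended_strand": _extended_strand,
    "ring_assembly": _ring_assembly,
    "multimodel": _multimodel,
    "biomt_assembly": _biomt_assembly,
}

FIXTURE_KINDS = tuple(sorted(_GENERATORS))


def make_fixture(kind: str, seed: int = 0, **params) -> str:
    """Generate the PDB text of a named fixture.

    Parameters specific to a kind are keyword arguments (e.g. ``d`` for
    ``dipeptide_at_distance``, ``orientation`` for ``aromatic_stack``,
    ``axial`` for ``cation_pi``, ``n`` for ``helix``/``sheet_pair``, ``k``
    for ``ring_assembly``/``biomt_assembly``).  All outputs are
    deterministic; the seed is reserved for kinds with randomized detail.
    """
    try:
        gen = _GENERATORS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; available: {', '.join(FIXTURE_KINDS)}"
        ) from None
    rng = np.random.default_rng(seed)
    return gen(rng=rng, **params)
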