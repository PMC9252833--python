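"""Physicochemical classification of residue-residue contacts.

Each contact can carry several labels at once (contacts are multivalent: a
salt bridge is usually also a hydrogen bond).  Four families of classifiers
are implemented:

* hydropathy pairing of amino acids (Kyte-Doolittle derived three-class
  partition: hydrophobic Phi, amphipathic gamma, hydrophilic zeta);
* electrostatics between charge groups (ion-ion > ion-dipole >
  dipole-dipole, by precedence);
* pi-electron interactions of aromatic rings (pi-pi parallel / T-shaped,
  cation-pi, anion-pi, dipole-pi);
* geometric hydrogen bonds from per-residue donor/acceptor tables
  (D-A distance, plus the D-H...A angle when hydrogens are present).

Hydropathy applies to proteins only; electrostatics and pi labels extend to
nucleotides through phosphate anions, base dipoles and base rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULT_THRESHOLDS, InteractionThresholds
from .contacts import Contact
from .structure import Chain, Residue, ResidueKind

__all__ = [
    "HYDROPHOBIC", "AMPHIPATHIC", "HYDROPHILIC",
    "hydropathy_class", "hydropathy_pair_label",
    "ChargeGroup", "find_charge_groups", "electrostatic_label",
    "AromaticRing", "find_rings", "pi_labels",
    "HBond", "detect_hbonds",
    "label_contacts", "filter_contacts",
    "residue_charge_sign",
    "DONORS", "ACCEPTORS",
]

# ---------------------------------------------------------------------------
# Hydropathy (three-class Kyte-Doolittle partition of the 20 amino acids)

HYDROPHOBIC = frozenset({"GLY", "ALA", "LEU", "ILE", "VAL", "PRO", "PHE"})   # Phi
AMPHIPATHIC = frozenset({"TRP", "TYR", "MET", "LYS"})                        # gamma
HYDROPHILIC = frozenset({"ARG", "ASN", "ASP", "GLN", "GLU", "HIS",           # zeta
                         "SER", "THR", "CYS"})

_CLASS_BY_NAME = (
    {n: "hydrophobic" for n in HYDROPHOBIC}
    | {n: "amphipathic" for n in AMPHIPATHIC}
    | {n: "hydrophilic" for n in HYDROPHILIC}
)


def hydropathy_class(residue_name: str) -> Optional[str]:
    """Hydropathy class of a standard amino acid; None for anything else."""
    return _CLASS_BY_NAME.get(residue_name.strip().upper())


def hydropathy_pair_label(contact: Contact) -> Optional[str]:
    """Pair label: same class -> that class; mixed classes -> 'mixed-hydropathy'.

    Pairs involving a non-amino-acid residue get no hydropathy label.
    """
    ca = hydropathy_class(contact.res_a.name)
    cb = hydropathy_class(contact.res_b.name)
    if ca is None or cb is None:
        return None
    return ca if ca == cb else "mixed-hydropathy"


# ---------------------------------------------------------------------------
# Charge groups

@dataclass(frozen=True)
class ChargeGroup:
    residue_id: tuple[str, int, str]
    kind: str  # "cation" | "anion" | "dipole"
    member_atoms: tuple[str, ...]
    point: np.ndarray  # representative point = centroid of members present

    def __hash__(self) -> int:
        return hash((self.residue_id, self.kind, self.member_atoms))


# side-chain group tables; only atoms actually present contribute to the centroid
_CATION_GROUPS = {
    "ARG": [("CZ", "NH1", "NH2", "NE")],
    "LYS": [("NZ",)],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],  # treated cationic (protonation unknown)
}
_ANION_GROUPS = {
    "ASP": [("CG", "OD1", "OD2")],
    "GLU": [("CD", "OE1", "OE2")],
}
_DIPOLE_GROUPS = {
    "SER": [("OG",)],
    "THR": [("OG1",)],
    "ASN": [("CG", "OD1", "ND2")],
    "GLN": [("CD", "OE1", "NE2")],
    "TYR": [("OH",)],
    "CYS": [("SG",)],
    "TRP": [("NE1",)],
}
_PHOSPHATE = ("P", "OP1", "OP2")
# polar base atoms per nucleobase -> one dipole group
_BASE_DIPOLES = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
    "DA": ("N1", "N3", "N6", "N7"),
    "DG": ("N1", "N2", "N3", "O6", "N7"),
    "DC": ("O2", "N3", "N4"),
    "DT": ("O2", "N3", "O4"),
}


def _group_centroid(residue: Residue, members: Sequence[str]) -> Optional[np.ndarray]:
    pts = [a.coords for name in members if (a := residue.atom(name)) is not None]
    if not pts:
        return None
    return np.mean(pts, axis=0)


def find_charge_groups(
    residue: Residue,
    is_n_terminus: bool = False,
    is_c_terminus: bool = False,
) -> list[ChargeGroup]:
    """Cation / anion / dipole groups hosted by one residue.

    A residue may host several groups (a nucleotide carries both a phosphate
    anion and a base dipole).  The representative point is the centroid of
    the member atoms present.
    """
    name = residue.name
    out: list[ChargeGroup] = []

    def add(kind: str, members: Sequence[str]) -> None:
        pt = _group_centroid(residue, members)
        if pt is not None:
            out.append(ChargeGroup(residue.id, kind, tuple(members), pt))

    if residue.kind is ResidueKind.AMINO_ACID:
        for members in _CATION_GROUPS.get(name, ()):
            add("cation", members)
        for members in _ANION_GROUPS.get(name, ()):
            add("anion", members)
        for members in _DIPOLE_GROUPS.get(name, ()):
            add("dipole", members)
        if is_n_terminus and residue.atom("N") is not None:
            add("cation", ("N",))
        if is_c_terminus and residue.atom("OXT") is not None:
            add("anion", ("C", "O", "OXT"))
    elif residue.kind in (ResidueKind.RIBONUCLEOTIDE, ResidueKind.DEOXYRIBONUCLEOTIDE):
        if residue.atom("P") is not None:
            add("anion", _PHOSPHATE)
        base = _BASE_DIPOLES.get(name)
        if base:
            add("dipole", base)
    return out


def charge_groups_for_chain(chain: Chain) -> dict[tuple[str, int, str], list[ChargeGroup]]:
    out = {}
    n = len(chain.residues)
    for i, r in enumerate(chain.residues):
        is_nt = i == 0 and r.kind is ResidueKind.AMINO_ACID
        is_ct = i == n - 1 and r.kind is ResidueKind.AMINO_ACID
        out[r.id] = find_charge_groups(r, is_n_terminus=is_nt, is_c_terminus=is_ct)
    return out


# attractive pairings only: like-charge proximity gets no electrostatic label
_ELECTROSTATIC_PRECEDENCE = {
    frozenset({"cation", "anion"}): "ion-ion",
    frozenset({"cation", "dipole"}): "ion-dipole",
    frozenset({"anion", "dipole"}): "ion-dipole",
    frozenset({"dipole"}): "dipole-dipole",
}
_LABEL_RANK = {"ion-ion": 0, "ion-dipole": 1, "dipole-dipole": 2}


def electrostatic_label(
    groups_a: Iterable[ChargeGroup],
    groups_b: Iterable[ChargeGroup],
    max_group_dist: float = DEFAULT_THRESHOLDS.max_group_dist,
) -> tuple[Optional[str], Optional[float]]:
    """Highest-precedence electrostatic label over qualifying group pairs.

    Only pairs whose representative points are within ``max_group_dist``
    qualify; precedence is ion-ion > ion-dipole > dipole-dipole.  Returns
    (label, group distance) or (None, None).  Like-charge pairs are still
    labelled ion-ion: the filter marks charge-charge proximity, not
    attraction.
    """
    best: tuple[int, float, str] | None = None
    for ga in groups_a:
        for gb in groups_b:
            d = float(np.linalg.norm(ga.point - gb.point))
            if d > max_group_dist:
                continue
            label = _ELECTROSTATIC_PRECEDENCE.get(frozenset({ga.kind, gb.kind}))
            if label is None:
                continue
            key = (_LABEL_RANK[label], d, label)
            if best is None or key < best:
                best = key
    if best is None:
        return None, None
    return best[2], best[1]


# ---------------------------------------------------------------------------
# Aromatic rings and pi interactions

@dataclass(frozen=True)
class AromaticRing:
    residue_id: tuple[str, int, str]
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray  # unit best-fit plane normal

    def __hash__(self) -> int:
        return hash((self.residue_id, self.atom_names))


_RING_TABLES: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}
_PURINE_RINGS = [("N1", "C2", "N3", "C4", "C5", "C6"),
                 ("C4", "C5", "N7", "C8", "N9")]
_PYRIMIDINE_RING = [("N1", "C2", "N3", "C4", "C5", "C6")]
for _code in ("A", "G", "DA", "DG"):
    _RING_TABLES[_code] = _PURINE_RINGS
for _code in ("C", "U", "DC", "DT"):
    _RING_TABLES[_code] = _PYRIMIDINE_RING


def _fit_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (smallest-spread singular vector)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    normal = vt[-1]
    return normal / np.linalg.norm(normal)


def find_rings(residue: Residue, warn: Optional[list[str]] = None) -> list[AromaticRing]:
    """Aromatic rings of a residue (Phe/Tyr/His single, Trp/purines two).

    The centroid is the mean of the ring-atom coordinates; the normal is the
    best-fit plane normal.  A ring missing more than one atom is skipped
    (optionally recording a warning).
    """
    tables = _RING_TABLES.get(residue.name)
    if not tables:
        return []
    out: list[AromaticRing] = []
    for names in tables:
        atoms = [a for n in names if (a := residue.atom(n)) is not None]
        if len(atoms) < len(names) - 1 or len(atoms) < 4:
            if warn is not None:
                warn.append(f"{residue.label}: ring {names} skipped, atoms missing")
            continue
        coords = np.array([a.coords for a in atoms])
        out.append(AromaticRing(
            residue_id=residue.id,
            atom_names=tuple(a.name for a in atoms),
            centroid=coords.mean(axis=0),
            normal=_fit_plane_normal(coords),
        ))
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(abs(c), 0.0, 1.0))))


def pi_labels(
    rings_a: Sequence[AromaticRing],
    rings_b: Sequence[AromaticRing],
    groups_a: Sequence[ChargeGroup],
    groups_b: Sequence[ChargeGroup],
    thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
) -> tuple[set[str], dict[str, float]]:
    """Pi-stacking labels for one residue pair.

    pi-pi: two ring centroids within ``d_pipi`` and normals parallel
    (<= ``a_par``) or perpendicular (within ``a_perp`` of 90 deg).
    cation-/anion-/dipole-pi: a charge group within ``d_x`` of a ring
    centroid and within ``a_axial`` of the ring normal axis.
    """
    labels: set[str] = set()
    geom: dict[str, float] = {}
    t = thresholds
    for ra in rings_a:
        for rb in rings_b:
            d = float(np.linalg.norm(ra.centroid - rb.centroid))
            if d > t.d_pipi:
                continue
            ang = _angle_deg(ra.normal, rb.normal)
            if ang <= t.a_par or abs(ang - 90.0) <= t.a_perp:
                labels.add("pi-pi")
                geom.setdefault("pipi_dist", d)
                geom.setdefault("pipi_angle", ang)

    def group_vs_rings(groups: Sequence[ChargeGroup], rings: Sequence[AromaticRing]) -> None:
        for g in groups:
            for ring in rings:
                v = g.point - ring.centroid
                d = float(np.linalg.norm(v))
                if d == 0.0 or d > t.d_x:
                    continue
                axial = _angle_deg(v, ring.normal)
                if axial <= t.a_axial:
                    labels.add(f"{g.kind}-pi")
                    geom.setdefault(f"{g.kind}_pi_dist", d)
                    geom.setdefault(f"{g.kind}_pi_angle", axial)

    group_vs_rings(groups_a, rings_b)
    group_vs_rings(groups_b, rings_a)
    return labels, geom


# ---------------------------------------------------------------------------
# Hydrogen bonds

# donor/acceptor heavy atoms by residue type; backbone handled separately
_SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "CYS": ("SG",),
}
_NUC_DONORS = {
    "A": ("N6",), "DA": ("N6",),
    "G": ("N1", "N2"), "DG": ("N1", "N2"),
    "C": ("N4",), "DC": ("N4",),
    "U": ("N3",), "DT": ("N3",),
}
_NUC_ACCEPTORS_BASE = {
    "A": ("N1", "N3", "N7"), "DA": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"), "DG": ("O6", "N3", "N7"),
    "C": ("O2", "N3"), "DC": ("O2", "N3"),
    "U": ("O2", "O4"), "DT": ("O2", "O4"),
}
_NUC_BACKBONE_ACCEPTORS = ("OP1", "OP2", "O3'", "O5'", "O4'", "O2'")
_NUC_BACKBONE_DONORS = ("O2'",)


def DONORS(residue: Residue) -> list[str]:
    """Heavy-atom H-bond donor names present in a residue."""
    names: list[str] = []
    if residue.kind is ResidueKind.AMINO_ACID:
        if residue.name != "PRO" and residue.atom("N") is not None:
            names.append("N")
        names += [n for n in _SIDECHAIN_DONORS.get(residue.name, ()) if residue.atom(n)]
    elif residue.kind in (ResidueKind.RIBONUCLEOTIDE, ResidueKind.DEOXYRIBONUCLEOTIDE):
        names += [n for n in _NUC_DONORS.get(residue.name, ()) if residue.atom(n)]
        names += [n for n in _NUC_BACKBONE_DONORS if residue.atom(n)]
    elif residue.kind is ResidueKind.WATER:
        if residue.atom("O") is not None:
            names.append("O")
    return names


def ACCEPTORS(residue: Residue) -> list[str]:
    """Heavy-atom H-bond acceptor names present in a residue."""
    names: list[str] = []
    if residue.kind is ResidueKind.AMINO_ACID:
        if residue.atom("O") is not None:
            names.append("O")
        if residue.atom("OXT") is not None:
            names.append("OXT")
        names += [n for n in _SIDECHAIN_ACCEPTORS.get(residue.name, ()) if residue.atom(n)]
    elif residue.kind in (ResidueKind.RIBONUCLEOTIDE, ResidueKind.DEOXYRIBONUCLEOTIDE):
        names += [n for n in _NUC_ACCEPTORS_BASE.get(residue.name, ()) if residue.atom(n)]
        names += [n for n in _NUC_BACKBONE_ACCEPTORS if residue.atom(n)]
    elif residue.kind is ResidueKind.WATER:
        if residue.atom("O") is not None:
            names.append("O")
    return names


@dataclass(frozen=True)
class HBond:
    donor_res: tuple[str, int, str]
    donor_atom: str
    acceptor_res: tuple[str, int, str]
    acceptor_atom: str
    distance: float
    angle: Optional[float]  # D-H...A, degrees; None when no H present


def _donor_hydrogens(residue: Residue, donor: "np.ndarray") -> list[np.ndarray]:
    """Hydrogens covalently attached to the donor (within 1.25 A)."""
    out = []
    for a in residue.atoms:
        if a.is_heavy:
            continue
        if np.linalg.norm(a.coords - donor) <= 1.25:
            out.append(a.coords)
    return out


def detect_hbonds(
    residues_a: Sequence[Residue],
    residues_b: Optional[Sequence[Residue]] = None,
    thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
) -> list[HBond]:
    """Geometric hydrogen-bond detection between (or within) residue sets.

    A donor-acceptor pair qualifies when the heavy-atom D-A distance is at
    most ``hb_da_max`` (default 3.5 A).  When the donor hydrogen is present
    in the structure, the D-H...A angle must additionally reach
    ``hb_dha_min`` (default 120 deg) for at least one attached hydrogen.
    Intra-residue pairs are never reported.  With one residue set, all
    residue pairs within the set are scanned; with two, only cross pairs.
    """
    t = thresholds
    same = residues_b is None
    rb = residues_a if same else residues_b
    out: list[HBond] = []
    seen: set[tuple] = set()
    pool_a = list(residues_a)
    pool_b = list(rb)

    def scan(donors_from: Sequence[Residue], acceptors_from: Sequence[Residue]) -> None:
        for res_d in donors_from:
            for dname in DONORS(res_d):
                datom = res_d.atom(dname)
                dpos = datom.coords
                hydrogens = _donor_hydrogens(res_d, dpos)
                for res_a in acceptors_from:
                    if res_a.id == res_d.id:
                        continue
                    for aname in ACCEPTORS(res_a):
                        apos = res_a.atom(aname).coords
                        d = float(np.linalg.norm(dpos - apos))
                        if d > t.hb_da_max or d < 0.5:
                            continue
                        angle: Optional[float] = None
                        if hydrogens:
                            # D-H...A angle measured at the hydrogen
                            best = max(
                                _point_angle_deg(dpos, h, apos) for h in hydrogens
                            )
                            if best < t.hb_dha_min:
                                continue
                            angle = best
                        key = (res_d.id, dname, res_a.id, aname)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.append(HBond(res_d.id, dname, res_a.id, aname, d, angle))

    if same:
        scan(pool_a, pool_a)
    else:
        scan(pool_a, pool_b)
        scan(pool_b, pool_a)
    out.sort(key=lambda h: (h.donor_res, h.donor_atom, h.acceptor_res, h.acceptor_atom))
    return out


def _point_angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Orchestration

def residue_charge_sign(residue_name: str) -> str:
    """'+' for Arg/Lys/His, '-' for Asp/Glu, '0' otherwise (1D charged track)."""
    n = residue_name.strip().upper()
    if n in ("ARG", "LYS", "HIS"):
        return "+"
    if n in ("ASP", "GLU"):
        return "-"
    return "0"


class ContactClassifier:
    """Precomputes per-residue groups/rings for a set of chains and labels contacts."""

    def __init__(self, chains: Sequence[Chain],
                 thresholds: InteractionThresholds = DEFAULT_THRESHOLDS):
        self.thresholds = thresholds
        self.groups: dict[tuple[str, int, str], list[ChargeGroup]] = {}
        self.rings: dict[tuple[str, int, str], list[AromaticRing]] = {}
        self._residues: dict[tuple[str, int, str], Residue] = {}
        for chain in chains:
            self.groups.update(charge_groups_for_chain(chain))
            for r in chain.residues:
                self.rings[r.id] = find_rings(r)
                self._residues[r.id] = r
        # hydrogen bonds over the full residue pool, indexed by residue pair
        self.hbonds = detect_hbonds(list(self._residues.values()), thresholds=thresholds)
        self._hb_pairs: dict[frozenset, list[HBond]] = {}
        for hb in self.hbonds:
            self._hb_pairs.setdefault(frozenset((hb.donor_res, hb.acceptor_res)), []).append(hb)

    def label(self, contact: Contact) -> Contact:
        """Populate the label set of one contact (in place; returns it)."""
        ida, idb = contact.res_a.id, contact.res_b.id
        hp = hydropathy_pair_label(contact)
        if hp is not None:
            contact.labels.add(hp)
        ga = self.groups.get(ida, [])
        gb = self.groups.get(idb, [])
        elabel, edist = electrostatic_label(ga, gb, self.thresholds.max_group_dist)
        if elabel is not None:
            contact.labels.add(elabel)
            contact.geometry["group_dist"] = edist
        plabels, pgeom = pi_labels(self.rings.get(ida, []), self.rings.get(idb, []),
                                   ga, gb, self.thresholds)
        contact.labels |= plabels
        contact.geometry.update(pgeom)
        hbs = self._hb_pairs.get(frozenset((ida, idb)))
        if hbs:
            contact.labels.add("hbond")
            contact.geometry["hb_da_dist"] = min(h.distance for h in hbs)
        return contact


def label_contacts(contacts: Sequence[Contact], chains: Sequence[Chain],
                   thresholds: InteractionThresholds = DEFAULT_THRESHOLDS) -> list[Contact]:
    """Label every contact with the union of all applicable classifier outputs."""
    clf = ContactClassifier(chains, thresholds)
    return [clf.label(c) for c in contacts]


def filter_contacts(contacts: Sequence[Contact], label: str) -> list[Contact]:
    """Contacts whose label set contains ``label`` (always a subset)."""
    return [c for c in contacts if label in c.labels]
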