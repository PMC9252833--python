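"""Per-residue 1D feature tracks displayed along the map axes.

Tracks: sequence composition, physicochemical properties (hydropathy class,
charge, hydrophobicity), three-state secondary structure from backbone
hydrogen-bond patterns, Shrake-Rupley solvent-accessible surface area,
sliding-window Shannon entropy, and hydrogen-bond donor/acceptor counts.

Secondary structure here is a deliberately simple geometric assignment
driven by backbone O...N distances (helix: the i -> i+4 pattern; strand:
two or more long-range or inter-chain pattern partners); it reproduces
ideal geometries and is not a DSSP/STRIDE replacement.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULT_ENTROPY_WINDOW, DEFAULT_PROBE_RADIUS, DEFAULT_SASA_POINTS
from .interactions import HBond, hydropathy_class, residue_charge_sign
from .structure import Chain, Residue, ResidueKind

__all__ = [
    "FeatureTrack",
    "composition_track",
    "composition_frequencies",
    "property_track",
    "secondary_structure",
    "sasa",
    "atom_sasa",
    "shannon_entropy_track",
    "donor_acceptor_track",
    "track_to_tsv",
    "VDW_RADII",
    "MAX_SASA_GXG",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class FeatureTrack:
    chain_id: str
    name: str
    kind: str  # "categorical" | "scalar"
    values: list
    units: str = ""
    residues: Optional[list[Residue]] = None

    def __len__(self) -> int:
        return len(self.values)


def one_letter(residue: Residue) -> str:
    if residue.kind is ResidueKind.AMINO_ACID:
        return AA_3TO1.get(residue.name, "X")
    if residue.kind in (ResidueKind.RIBONUCLEOTIDE, ResidueKind.DEOXYRIBONUCLEOTIDE):
        return residue.name[-1] if residue.name[-1] in "AUGCTI" else "X"
    return "X"


def composition_track(chain: Chain) -> FeatureTrack:
    """Per-residue one-letter code track."""
    if len(chain) == 0:
        raise ValueError(f"chain {chain.id} is empty")
    codes = [one_letter(r) for r in chain.residues]
    return FeatureTrack(chain.id, "composition", "categorical", codes,
                        residues=list(chain.residues))


def composition_frequencies(chain: Chain) -> dict[str, float]:
    """Chain-level residue-type frequency table (sums to 1)."""
    codes = [one_letter(r) for r in chain.residues]
    n = len(codes)
    if n == 0:
        raise ValueError(f"chain {chain.id} is empty")
    counts = Counter(codes)
    return {c: counts[c] / n for c in sorted(counts)}


def property_track(chain: Chain, prop: str) -> FeatureTrack:
    """Categorical property track: hydropathy_class, charged, or hydrophobic.

    Hydropathy-derived tracks are protein-only.
    """
    from .structure import PolymerType

    if prop not in ("hydropathy_class", "charged", "hydrophobic"):
        raise ValueError(f"unknown property {prop!r}")
    if chain.polymer_type is not PolymerType.PROTEIN:
        raise ValueError(
            f"property {prop!r} requires a protein chain; chain {chain.id} "
            f"is {chain.polymer_type.value}"
        )
    values: list[str] = []
    for r in chain.residues:
        if prop == "charged":
            values.append(residue_charge_sign(r.name))
        elif prop == "hydrophobic":
            values.append("1" if hydropathy_class(r.name) == "hydrophobic" else "0")
        else:
            cls = hydropathy_class(r.name)
            values.append({"hydrophobic": "Phi", "amphipathic": "gamma",
                           "hydrophilic": "zeta"}.get(cls, "X"))
    return FeatureTrack(chain.id, prop, "categorical", values,
                        residues=list(chain.residues))


# ---------------------------------------------------------------------------
# Secondary structure

_HB_ON_MAX = 3.5  # backbone O...N pattern distance, Angstroms


def _backbone(residue: Residue, name: str) -> Optional[np.ndarray]:
    a = residue.atom(name)
    return None if a is None else a.coords


def secondary_structure(chain: Chain, partner_chains: Sequence[Chain] = ()) -> FeatureTrack:
    """Three-state (H/E/C) assignment from backbone O...N distance patterns.

    H: runs where the carbonyl O of residue i sits within 3.5 A of the
    backbone N of residue i+4, for >= 4 consecutive i.  E: a residue with
    >= 2 pattern partners at sequence separation > 4 (or on another chain).
    C: everything else, including residues with missing backbone atoms.
    """
    n = len(chain)
    ss = ["C"] * n
    N = [_backbone(r, "N") for r in chain.residues]
    O = [_backbone(r, "O") for r in chain.residues]

    # helix: i -> i+4 O...N pattern
    hb4 = [False] * n
    for i in range(n - 4):
        if O[i] is not None and N[i + 4] is not None:
            hb4[i] = float(np.linalg.norm(O[i] - N[i + 4])) <= _HB_ON_MAX
    i = 0
    while i < n:
        if hb4[i]:
            j = i
            while j < n and hb4[j]:
                j += 1
            if j - i >= 4:
                for k in range(i, min(j + 4, n)):
                    ss[k] = "H"
            i = j
        else:
            i += 1

    # strand: long-range / inter-chain O...N pattern partners
    def pattern_partners(i: int) -> int:
        count = 0
        for j in range(n):
            if abs(i - j) <= 4:
                continue
            if O[i] is not None and N[j] is not None and \
                    np.linalg.norm(O[i] - N[j]) <= _HB_ON_MAX:
                count += 1
            if N[i] is not None and O[j] is not None and \
                    np.linalg.norm(N[i] - O[j]) <= _HB_ON_MAX:
                count += 1
        for other in partner_chains:
            if other is chain:
                continue
            for r in other.residues:
                No = _backbone(r, "N")
                Oo = _backbone(r, "O")
                if O[i] is not None and No is not None and \
                        np.linalg.norm(O[i] - No) <= _HB_ON_MAX:
                    count += 1
                if N[i] is not None and Oo is not None and \
                        np.linalg.norm(N[i] - Oo) <= _HB_ON_MAX:
                    count += 1
        return count

    for i in range(n):
        if ss[i] == "H":
            continue
        if pattern_partners(i) >= 2:
            ss[i] = "E"

    return FeatureTrack(chain.id, "secondary_structure", "categorical", ss,
                        residues=list(chain.residues))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

#: van der Waals radii, Angstroms (Bondi-style; default 1.8 for unknowns)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "D": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85,
             "SE": 1.90, "I": 1.98}
_DEFAULT_RADIUS = 1.8

#: Theoretical maximum SASA of residue X in an extended Gly-X-Gly tripeptide,
#: Angstrom^2 (Tien et al. 2013 theoretical values); used for relative SASA.
MAX_SASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area by Shrake-Rupley sphere sampling.

    Each atom's solvent-extended sphere (r_vdw + probe) is sampled on a
    deterministic spiral lattice; a point is accessible when it lies outside
    every neighbour's extended sphere.  Area = accessible fraction times the
    full sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    ext = radii + probe_radius
    unit = _sphere_points(n_points)
    out = np.zeros(n)
    tree = cKDTree(coords)
    max_ext = ext.max() if n else 0.0
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        out[i] = accessible.mean() * 4.0 * math.pi * ext[i] ** 2
    return out


def sasa(
    chains: Sequence[Chain],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    relative: bool = False,
) -> dict[str, FeatureTrack]:
    """Per-residue SASA tracks for a set of chains, in one joint calculation.

    Heavy atoms only.  With ``relative=True`` values are divided by the
    Gly-X-Gly reference maximum for the residue type (NaN-free: residues
    without a reference keep absolute area).
    """
    coords_list, radii_list, owners = [], [], []
    for ci, chain in enumerate(chains):
        for ri, r in enumerate(chain.residues):
            for a in r.heavy_atoms():
                coords_list.append(a.coords)
                radii_list.append(VDW_RADII.get(a.element, _DEFAULT_RADIUS))
                owners.append((ci, ri))
    if not coords_list:
        raise ValueError("no heavy atoms")
    areas = atom_sasa(np.array(coords_list), np.array(radii_list),
                      probe_radius, n_points)
    per_res: dict[tuple[int, int], float] = {}
    for (ci, ri), a in zip(owners, areas):
        per_res[(ci, ri)] = per_res.get((ci, ri), 0.0) + float(a)
    tracks: dict[str, FeatureTrack] = {}
    for ci, chain in enumerate(chains):
        vals = []
        for ri, r in enumerate(chain.residues):
            v = per_res.get((ci, ri), 0.0)
            if relative:
                ref = MAX_SASA_GXG.get(r.name)
                if ref:
                    v = v / ref
            vals.append(v)
        tracks[chain.id] = FeatureTrack(
            chain.id, "relative_sasa" if relative else "sasa", "scalar", vals,
            units="" if relative else "A^2", residues=list(chain.residues))
    return tracks


# ---------------------------------------------------------------------------
# Shannon entropy

def shannon_entropy_track(chain: Chain, window: int = DEFAULT_ENTROPY_WINDOW) -> FeatureTrack:
    """Sliding-window Shannon entropy (bits) of residue-type frequencies.

    The window is centered on each position and truncated at the termini.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    codes = [one_letter(r) for r in chain.residues]
    half = window // 2
    n = len(codes)
    vals: list[float] = []
    for i in range(n):
        seg = codes[max(0, i - half): min(n, i + half + 1)]
        counts = np.array(list(Counter(seg).values()), dtype=float)
        p = counts / counts.sum()
        vals.append(float(-(p * np.log2(p)).sum()))
    return FeatureTrack(chain.id, "shannon_entropy", "scalar", vals, units="bits",
                        residues=list(chain.residues))


# ---------------------------------------------------------------------------
# H-bond donor/acceptor counts

def donor_acceptor_track(chain: Chain, hbonds: Sequence[HBond]) -> tuple[FeatureTrack, FeatureTrack]:
    """Per-residue counts of hydrogen bonds donated and accepted."""
    don = Counter(h.donor_res for h in hbonds)
    acc = Counter(h.acceptor_res for h in hbonds)
    d_vals = [don.get(r.id, 0) for r in chain.residues]
    a_vals = [acc.get(r.id, 0) for r in chain.residues]
    res = list(chain.residues)
    return (
        FeatureTrack(chain.id, "hbond_donor_count", "scalar", d_vals, residues=res),
        FeatureTrack(chain.id, "hbond_acceptor_count", "scalar", a_vals, residues=res),
    )


def track_to_tsv(track: FeatureTrack) -> str:
    """TSV export: ordinal, resnum, icode, resname, value."""
    rows = ["\t".join(["ordinal", "resnum", "icode", "resname", track.name])]
    residues = track.residues or [None] * len(track.values)
    for i, (r, v) in enumerate(zip(residues, track.values)):
        val = f"{v:.4f}" if isinstance(v, float) else str(v)
        if r is None:
            rows.append(f"{i}\t.\t.\t.\t{val}")
        else:
            rows.append(f"{i}\t{r.seq_num}\t{r.icode or '.'}\t{r.name}\t{val}")
    return "\n".join(rows) + "\n"
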