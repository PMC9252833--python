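"""Minimal heavy-atom distances, distance matrices and contact maps.

The contact definition: two residues are in contact when the distance
between their two closest heavy atoms (any atoms that are not hydrogens) is
strictly below the cutoff.  Intramolecular maps additionally support a
sequence-separation filter that drops pairs within ``n`` positions along the
chain (measured on file-order ordinals, so numbering gaps and insertion
codes cannot corrupt it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Chain, Residue

__all__ = [
    "ResiduePairDistance",
    "DistanceMatrix",
    "ContactMap",
    "Contact",
    "min_heavy_distance",
    "distance_matrix",
    "contact_map",
    "contact_list",
    "contacts_to_tsv",
    "distance_matrix_to_tsv",
]


@dataclass(frozen=True)
class ResiduePairDistance:
    res_a: tuple[str, int, str]
    res_b: tuple[str, int, str]
    min_dist: float
    closest_atoms: tuple[str, str]


@dataclass
class Contact:
    """A residue pair below the cutoff, carrying a set of interaction labels."""

    res_a: Residue
    res_b: Residue
    min_dist: float
    closest_atoms: tuple[str, str]
    labels: set[str] = field(default_factory=set)
    geometry: dict[str, float] = field(default_factory=dict)


def min_heavy_distance(res_a: Residue, res_b: Residue) -> ResiduePairDistance:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues.

    Ties on the minimum are broken toward the lexicographically smallest
    (atom_a, atom_b) name pair.
    """
    heavy_a = res_a.heavy_atoms()
    heavy_b = res_b.heavy_atoms()
    if not heavy_a:
        raise ValueError(f"residue {res_a.label} has no heavy atoms")
    if not heavy_b:
        raise ValueError(f"residue {res_b.label} has no heavy atoms")
    xa = np.array([a.coords for a in heavy_a])
    xb = np.array([a.coords for a in heavy_b])
    d = cdist(xa, xb)
    dmin = d.min()
    ii, jj = np.nonzero(d == dmin)
    pairs = sorted((heavy_a[i].name, heavy_b[j].name) for i, j in zip(ii, jj))
    return ResiduePairDistance(res_a.id, res_b.id, float(dmin), pairs[0])


@dataclass
class DistanceMatrix:
    """Per-residue-pair minimal heavy-atom distances.

    ``values[i, j]`` is the distance between ``axis_y[i]`` and ``axis_x[j]``.
    ``mode`` is ``"intra"`` when both axes are the same chain (then the
    matrix is square and symmetric with a zero diagonal by convention) and
    ``"inter"`` otherwise.
    """

    axis_x: list[Residue]
    axis_y: list[Residue]
    values: np.ndarray
    mode: str
    chain_x: str = ""
    chain_y: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _residue_atom_table(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coordinates with a per-atom residue index."""
    coords = []
    owner = []
    for i, r in enumerate(chain.residues):
        hc = r.heavy_coords()
        if hc.size == 0:
            raise ValueError(f"residue {r.label} has no heavy atoms")
        coords.append(hc)
        owner.append(np.full(len(hc), i))
    return np.concatenate(coords), np.concatenate(owner)


def distance_matrix(chain_a: Chain, chain_b: Optional[Chain] = None) -> DistanceMatrix:
    """Minimal heavy-atom distance matrix for one chain (intra) or two (inter).

    The computation vectorizes the all-atom distance matrix and reduces it to
    residue pairs with a segmented minimum; tests pin it to the naive
    double loop.
    """
    intra = chain_b is None or chain_b is chain_a
    chain_y = chain_a
    chain_x = chain_a if intra else chain_b
    if len(chain_y) == 0 or len(chain_x) == 0:
        raise ValueError("empty chain")

    ca, oa = _residue_atom_table(chain_y)
    if intra:
        cb, ob = ca, oa
    else:
        cb, ob = _residue_atom_table(chain_x)

    ny, nx = len(chain_y), len(chain_x)
    d_atoms = cdist(ca, cb)
    values = np.full((ny, nx), np.inf)
    # segmented min over residue-pair blocks
    iy = np.broadcast_to(oa[:, None], d_atoms.shape)
    ix = np.broadcast_to(ob[None, :], d_atoms.shape)
    np.minimum.at(values, (iy, ix), d_atoms)
    if intra:
        values = np.minimum(values, values.T)  # exact symmetry
        np.fill_diagonal(values, 0.0)  # self-distance is 0 by convention
    return DistanceMatrix(
        axis_x=list(chain_x.residues),
        axis_y=list(chain_y.residues),
        values=values,
        mode="intra" if intra else "inter",
        chain_x=chain_x.id,
        chain_y=chain_y.id,
    )


@dataclass
class ContactMap:
    axis_x: list[Residue]
    axis_y: list[Residue]
    values: np.ndarray
    mask: np.ndarray
    cutoff: float
    mode: str
    excluded_neighbors: int = 0
    chain_x: str = ""
    chain_y: str = ""


def contact_map(dm: DistanceMatrix, cutoff: float, exclude_neighbors: int = 0) -> ContactMap:
    """Boolean contact map: distance strictly below the cutoff.

    A pair at exactly the cutoff is NOT a contact.  In intra mode, pairs
    with ordinal separation <= ``exclude_neighbors`` are masked off (the
    diagonal, separation 0, is always off); the filter is ignored in inter
    mode.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if exclude_neighbors < 0:
        raise ValueError(f"exclude_neighbors must be >= 0, got {exclude_neighbors}")
    mask = dm.values < cutoff
    n = exclude_neighbors if dm.mode == "intra" else 0
    if dm.mode == "intra":
        ny = len(dm.axis_y)
        sep = np.abs(np.arange(ny)[:, None] - np.arange(ny)[None, :])
        mask &= sep > n
    return ContactMap(
        axis_x=dm.axis_x,
        axis_y=dm.axis_y,
        values=dm.values,
        mask=mask,
        cutoff=cutoff,
        mode=dm.mode,
        excluded_neighbors=n,
        chain_x=dm.chain_x,
        chain_y=dm.chain_y,
    )


def contact_list(cm: ContactMap) -> list[Contact]:
    """One :class:`Contact` per true mask cell, sorted by (ordinal_i, ordinal_j).

    Intra maps report the upper triangle only, so each pair appears once.
    """
    out: list[Contact] = []
    ii, jj = np.nonzero(cm.mask)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if cm.mode == "intra" and j <= i:
            continue
        ra, rb = cm.axis_y[i], cm.axis_x[j]
        rpd = min_heavy_distance(ra, rb)
        out.append(Contact(res_a=ra, res_b=rb, min_dist=rpd.min_dist,
                           closest_atoms=rpd.closest_atoms))
    return out


def contacts_to_tsv(contacts: list[Contact]) -> str:
    """Contact-list text export (the downloadable raw-data table)."""
    header = "\t".join([
        "chain_a", "resnum_a", "icode_a", "resname_a",
        "chain_b", "resnum_b", "icode_b", "resname_b",
        "min_dist_A", "atom_a", "atom_b", "labels",
    ])
    rows = [header]
    for c in contacts:
        rows.append("\t".join([
            c.res_a.chain_id, str(c.res_a.seq_num), c.res_a.icode or ".",
            c.res_a.name,
            c.res_b.chain_id, str(c.res_b.seq_num), c.res_b.icode or ".",
            c.res_b.name,
            f"{c.min_dist:.3f}", c.closest_atoms[0], c.closest_atoms[1],
            ";".join(sorted(c.labels)) or ".",
        ]))
    return "\n".join(rows) + "\n"


def _res_tag(r: Residue) -> str:
    return f"{r.chain_id}:{r.name}:{r.seq_num}{r.icode}"


def distance_matrix_to_tsv(dm: DistanceMatrix) -> str:
    """Distance matrix export with residue-identifier header row/column."""
    header = "\t".join([""] + [_res_tag(r) for r in dm.axis_x])
    rows = [header]
    for i, r in enumerate(dm.axis_y):
        rows.append("\t".join([_res_tag(r)] + [f"{v:.3f}" for v in dm.values[i]]))
    return "\n".join(rows) + "\n"
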