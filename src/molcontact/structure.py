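"""PDB parsing into a typed model->chain->residue->atom hierarchy.

Parsing is delegated to gemmi; this module converts gemmi's structure into a
small, explicit container tailored to contact-map analysis: hydrogens are
kept but flagged, waters are dropped by default, alternate locations are
resolved by a policy, and chains are classified by polymer type.  Biological
assemblies are rebuilt from the REMARK 350 BIOMT operators that gemmi
exposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AssemblyTransform",
    "PolymerType",
    "ResidueKind",
    "ParseError",
    "ParseReport",
    "parse_pdb",
    "parse_pdb_file",
    "classify_chain",
    "apply_assembly",
    "select_model",
    "write_pdb",
]

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL""".split()
)
RIBONUCLEOTIDES = frozenset({"A", "U", "G", "C", "I"})
DEOXYNUCLEOTIDES = frozenset({"DA", "DT", "DG", "DC", "DU", "DI"})
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class ResidueKind(Enum):
    AMINO_ACID = "amino_acid"
    RIBONUCLEOTIDE = "ribonucleotide"
    DEOXYRIBONUCLEOTIDE = "deoxyribonucleotide"
    WATER = "water"
    OTHER = "other"


class PolymerType(Enum):
    PROTEIN = "protein"
    RNA = "rna"
    DNA = "dna"
    HYBRID = "hybrid"
    OTHER = "other"

    @property
    def is_nucleic(self) -> bool:
        return self in (PolymerType.RNA, PolymerType.DNA)


class ParseError(ValueError):
    """Raised when the input cannot be interpreted as a PDB structure."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstroms
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.altloc, self.occupancy)


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    name: str
    atoms: list[Atom]
    kind: ResidueKind

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain_id}/{self.name}{self.seq_num}{ic}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.seq_num,
            self.icode,
            self.name,
            [a.copy() for a in self.atoms],
            self.kind,
        )


@dataclass
class Chain:
    id: str
    residues: list[Residue]
    polymer_type: PolymerType = PolymerType.OTHER

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence_index(self) -> dict[tuple[str, int, str], int]:
        """Residue id -> 0-based ordinal, in file order."""
        return {r.id: i for i, r in enumerate(self.residues)}

    def copy(self, new_id: Optional[str] = None) -> "Chain":
        cid = self.id if new_id is None else new_id
        residues = []
        for r in self.residues:
            rc = r.copy()
            rc.chain_id = cid
            residues.append(rc)
        return Chain(cid, residues, self.polymer_type)


@dataclass
class AssemblyTransform:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,)
    assembly_id: str
    target_chains: list[str]

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-4):
            raise ValueError(f"assembly {self.assembly_id}: rotation is not orthonormal")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ParseReport:
    """Defects and decisions recorded while parsing (stands in for repair)."""

    source_name: str = ""
    n_atoms: int = 0
    n_hydrogens: int = 0
    n_waters_excluded: int = 0
    n_altloc_dropped: int = 0
    n_hetero_residues: int = 0
    skipped_lines: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"source: {self.source_name}",
            f"atoms parsed: {self.n_atoms}",
            f"hydrogens (flagged non-heavy): {self.n_hydrogens}",
            f"water molecules excluded: {self.n_waters_excluded}",
            f"alternate-location atoms dropped: {self.n_altloc_dropped}",
            f"non-water hetero residues: {self.n_hetero_residues}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        for s in self.skipped_lines:
            lines.append(f"skipped: {s}")
        return "\n".join(lines) + "\n"


@dataclass
class Structure:
    models: list[list[Chain]]
    header_transforms: list[AssemblyTransform] = field(default_factory=list)
    source_name: str = ""
    report: ParseReport = field(default_factory=ParseReport)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model(self, index: int = 1) -> list[Chain]:
        """1-based model access."""
        if not 1 <= index <= len(self.models):
            raise IndexError(
                f"model {index} requested, {len(self.models)} present"
            )
        return self.models[index - 1]

    def chain(self, chain_id: str, model_index: int = 1) -> Chain:
        for ch in self.model(model_index):
            if ch.id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}; available: "
                       f"{[c.id for c in self.model(model_index)]}")

    def assembly_ids(self) -> list[str]:
        seen: list[str] = []
        for t in self.header_transforms:
            if t.assembly_id not in seen:
                seen.append(t.assembly_id)
        return seen


def residue_kind(name: str) -> ResidueKind:
    name = name.strip().upper()
    if name in STANDARD_AMINO_ACIDS:
        return ResidueKind.AMINO_ACID
    if name in RIBONUCLEOTIDES:
        return ResidueKind.RIBONUCLEOTIDE
    if name in DEOXYNUCLEOTIDES:
        return ResidueKind.DEOXYRIBONUCLEOTIDE
    if name in WATER_NAMES:
        return ResidueKind.WATER
    return ResidueKind.OTHER


def classify_chain(chain: Chain) -> PolymerType:
    """Classify a chain by the majority residue kind.

    Protein when most residues are standard amino acids; rna/dna by
    nucleotide codes; hybrid when amino acids and nucleotides both make up
    at least 20% of the chain; otherwise ``other``.
    """
    counts = {k: 0 for k in ResidueKind}
    n = 0
    for r in chain.residues:
        if r.kind is ResidueKind.WATER:
            continue
        counts[r.kind] += 1
        n += 1
    if n == 0:
        return PolymerType.OTHER
    aa = counts[ResidueKind.AMINO_ACID] / n
    ribo = counts[ResidueKind.RIBONUCLEOTIDE] / n
    deoxy = counts[ResidueKind.DEOXYRIBONUCLEOTIDE] / n
    nuc = ribo + deoxy
    if aa >= 0.2 and nuc >= 0.2:
        return PolymerType.HYBRID
    if aa > 0.5:
        return PolymerType.PROTEIN
    if nuc > 0.5:
        return PolymerType.RNA if ribo >= deoxy else PolymerType.DNA
    return PolymerType.OTHER


_ALTLOC_POLICIES = ("highest_occupancy", "first", "all")


def _resolve_altlocs(atoms: list[Atom], policy: str) -> tuple[list[Atom], int]:
    """Keep one conformer per atom name according to the policy.

    ``highest_occupancy`` keeps the conformer with the largest occupancy,
    ties broken by altloc letter order; ``first`` keeps the first seen;
    ``all`` keeps everything.
    """
    if policy == "all":
        return atoms, 0
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    dropped = 0
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
            continue
        dropped += 1
        if policy == "highest_occupancy":
            cur = by_name[a.name]
            if (a.occupancy, _altloc_rank(a.altloc)) > (
                cur.occupancy,
                _altloc_rank(cur.altloc),
            ):
                by_name[a.name] = a
    return [by_name[n] for n in order], dropped


def _altloc_rank(altloc: str) -> float:
    # earlier letters win a tie: rank 'A' above 'B'
    return -ord(altloc) if altloc else 0.0


def _first_offending_line(text: str) -> str:
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if not line.strip():
            continue
        if rec not in {
            "ATOM", "HETATM", "MODEL", "ENDMDL", "TER", "END", "REMARK",
            "HEADER", "TITLE", "COMPND", "SOURCE", "KEYWDS", "EXPDTA",
            "AUTHOR", "REVDAT", "JRNL", "SEQRES", "HELIX", "SHEET", "SSBOND",
            "LINK", "CISPEP", "SITE", "CRYST1", "ORIGX1", "ORIGX2", "ORIGX3",
            "SCALE1", "SCALE2", "SCALE3", "MTRIX1", "MTRIX2", "MTRIX3",
            "CONECT", "MASTER", "ANISOU", "HETNAM", "HET", "FORMUL", "SEQADV",
            "MODRES", "DBREF", "CAVEAT", "OBSLTE", "SPLIT", "SPRSDE", "NUMMDL",
        }:
            return f"line {i}: {line.rstrip()}"
    return "no ATOM/HETATM records found"


def parse_pdb(
    text: str,
    include_waters: bool = False,
    altloc_policy: str = "highest_occupancy",
    source_name: str = "<string>",
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Hydrogens are retained but flagged non-heavy; waters are excluded unless
    ``include_waters``; alternate locations resolved per ``altloc_policy``
    (``highest_occupancy`` | ``first`` | ``all``).  MODEL/ENDMDL records
    delimit models; models whose chain sets disagree are truncated to the
    common chains with a warning in the parse report.
    """
    if altloc_policy not in _ALTLOC_POLICIES:
        raise ValueError(
            f"unknown altloc policy {altloc_policy!r}; choose from {_ALTLOC_POLICIES}"
        )
    if not text.strip():
        raise ParseError("empty input: no ATOM/HETATM records")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"unparseable PDB input ({exc}); {_first_offending_line(text)}") from exc

    report = ParseReport(source_name=source_name)
    models: list[list[Chain]] = []
    for gm in st:
        chains: list[Chain] = []
        for gch in gm:
            residues: list[Residue] = []
            for gres in gch:
                kind = residue_kind(gres.name)
                if kind is ResidueKind.WATER and not include_waters:
                    report.n_waters_excluded += 1
                    continue
                atoms: list[Atom] = []
                for ga in gres:
                    altloc = ga.altloc if ga.altloc and ga.altloc != "\x00" else ""
                    atom = Atom(
                        name=ga.name,
                        element=ga.element.name.upper(),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                        altloc=altloc,
                        occupancy=float(ga.occ),
                    )
                    if not np.all(np.isfinite(atom.coords)):
                        report.skipped_lines.append(
                            f"non-finite coordinates: {gch.name}/{gres.name}{gres.seqid.num}/{ga.name}"
                        )
                        continue
                    atoms.append(atom)
                atoms, dropped = _resolve_altlocs(atoms, altloc_policy)
                report.n_altloc_dropped += dropped
                if not atoms:
                    continue
                if kind is ResidueKind.OTHER:
                    report.n_hetero_residues += 1
                report.n_atoms += len(atoms)
                report.n_hydrogens += sum(1 for a in atoms if not a.is_heavy)
                residues.append(
                    Residue(
                        chain_id=gch.name,
                        seq_num=gres.seqid.num,
                        icode=(gres.seqid.icode or "").strip(),
                        name=gres.name.strip().upper(),
                        atoms=atoms,
                        kind=kind,
                    )
                )
            if residues:
                chains.append(Chain(gch.name, residues))
        if chains:
            models.append(chains)

    if not models:
        raise ParseError(f"no atoms parsed; {_first_offending_line(text)}")

    # reconcile multi-model chain sets
    if len(models) > 1:
        common = set(c.id for c in models[0])
        for m in models[1:]:
            common &= set(c.id for c in m)
        if any(len(m) != len(common) for m in models):
            report.warnings.append(
                "models disagree on chain ids; truncated to common chains "
                f"{sorted(common)}"
            )
            models = [[c for c in m if c.id in common] for m in models]
            if not all(models):
                raise ParseError("multi-model input has no common chains")

    for m in models:
        for ch in m:
            ch.polymer_type = classify_chain(ch)

    transforms = _assembly_transforms(st)
    return Structure(models=models, header_transforms=transforms,
                     source_name=source_name, report=report)


def parse_pdb_file(path: str, **kwargs) -> Structure:
    with open(path) as fh:
        text = fh.read()
    kwargs.setdefault("source_name", path)
    return parse_pdb(text, **kwargs)


def _assembly_transforms(st: gemmi.Structure) -> list[AssemblyTransform]:
    out: list[AssemblyTransform] = []
    for asm in st.assemblies:
        for gen in asm.generators:
            chains = list(gen.chains)
            for op in gen.operators:
                t = op.transform
                out.append(
                    AssemblyTransform(
                        rotation=np.array(t.mat.tolist(), dtype=float),
                        translation=np.array([t.vec.x, t.vec.y, t.vec.z], dtype=float),
                        assembly_id=str(asm.name),
                        target_chains=chains,
                    )
                )
    return out


def select_model(structure: Structure, index: int) -> Structure:
    """Return a single-model Structure holding model ``index`` (1-based)."""
    chains = structure.model(index)  # raises with model count on bad index
    return Structure(
        models=[[ch.copy() for ch in chains]],
        header_transforms=list(structure.header_transforms),
        source_name=structure.source_name,
        report=structure.report,
    )


def apply_assembly(structure: Structure, which: str) -> Structure:
    """Expand a biological assembly by applying its BIOMT operators.

    Each operator produces transformed copies of its target chains; copies
    get deterministic derived ids (original id + 1-based operator ordinal,
    the identity copy keeping the bare id when it is the first operator).
    """
    which = str(which)
    transforms = [t for t in structure.header_transforms if t.assembly_id == which]
    if not transforms:
        avail = structure.assembly_ids()
        raise KeyError(
            f"assembly {which!r} not present; available assemblies: {avail or 'none'}"
        )
    new_models: list[list[Chain]] = []
    for chains in structure.models:
        by_id = {c.id: c for c in chains}
        out: list[Chain] = []
        counters: dict[str, int] = {}
        for t in transforms:
            identity = (
                np.allclose(t.rotation, np.eye(3), atol=1e-9)
                and np.allclose(t.translation, 0.0, atol=1e-9)
            )
            for cid in t.target_chains:
                if cid not in by_id:
                    continue
                k = counters.get(cid, 0)
                counters[cid] = k + 1
                new_id = cid if (k == 0 and identity) else f"{cid}{k + 1}"
                copy = by_id[cid].copy(new_id=new_id)
                for r in copy.residues:
                    for a in r.atoms:
                        a.coords = t.apply(a.coords)
                out.append(copy)
        new_models.append(out)
    return Structure(
        models=new_models,
        header_transforms=list(structure.header_transforms),
        source_name=structure.source_name,
        report=structure.report,
    )


def write_pdb(structure: Structure) -> str:
    """Serialize back to PDB text (ATOM/HETATM, MODEL/ENDMDL, TER, END)."""
    lines: list[str] = []
    multi = structure.n_models > 1
    serial = 1
    for mi, chains in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for ch in chains:
            for r in ch.residues:
                record = "ATOM" if r.kind in (
                    ResidueKind.AMINO_ACID,
                    ResidueKind.RIBONUCLEOTIDE,
                    ResidueKind.DEOXYRIBONUCLEOTIDE,
                ) else "HETATM"
                for a in r.atoms:
                    name = a.name
                    # PDB atom-name column convention: 1-char elements start col 14
                    if len(name) < 4 and len(a.element) == 1:
                        name = f" {name}"
                    x, y, z = a.coords
                    lines.append(
                        f"{record:<6s}{serial:5d} {name:<4s}{a.altloc or ' '}"
                        f"{r.name:>3s} {ch.id[:1]}{r.seq_num:4d}{r.icode or ' '}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                        f"          {a.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {ch.residues[-1].name:>3s} "
                         f"{ch.id[:1]}{ch.residues[-1].seq_num:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
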