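"""Readers and writers for the standard formats the pipeline touches.

FASTA (sequences and alignments), Newick trees with branch supports,
PDB-format coordinates, and the two CSV table schemas (kinetics and
structure annotations).  Every other module consumes these formats
through this module only.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .kinetics import KineticRecord
from .structure import StructureAnnotation

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues legal inside sequences; "." is normalized to "-" on read
VALID_RESIDUES = frozenset(AA20) | {"X", GAP}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        if not set(self.residues) <= VALID_RESIDUES:
            for pos, ch in enumerate(self.residues):
                if ch not in VALID_RESIDUES:
                    raise FormatError(
                        f"sequence {self.id!r}: invalid residue {ch!r} at position {pos + 1}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def ungap(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.ungapped(), self.description)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Residues are uppercased, line wrapping removed and "." gaps normalized
    to "-".  Duplicate ids, empty sequences and non-amino-acid characters
    raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(".", GAP)
        records.append(SequenceRecord(rec.id, residues, rec.description))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate sequence ids: {', '.join(dupes)}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    header = desc
                else:
                    header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick

_NUMERIC = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _check_parens(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise FormatError(f"unbalanced '(': {depth} unclosed at end of input")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a support-annotated tree.

    Numeric internal-node labels are interpreted as branch supports;
    values in (1, 100] are treated as bootstrap percentages and divided
    by 100.  Non-numeric labels are kept as clade names.  Missing branch
    lengths become 0.
    """
    _check_parens(text)
    tree = TreeNode.read(_io.StringIO(text), convert_underscores=False)
    leaves = [t.name for t in tree.tips()]
    dupes = sorted({n for n in leaves if leaves.count(n) > 1})
    if dupes:
        raise FormatError(f"duplicate leaf labels: {', '.join(dupes)}")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if node.is_tip():
            node.support = None
            continue
        label = node.name
        if label is not None and _NUMERIC.match(str(label)):
            val = float(label)
            if 1.0 < val <= 100.0:
                val /= 100.0
            if not 0.0 <= val <= 1.0:
                raise FormatError(f"support value {label!r} outside [0, 100]")
            node.support = val
            node.name = None
        else:
            node.support = None
    return tree


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def tree_to_newick(tree: TreeNode) -> str:
    """Serialize a tree, writing supports back as internal-node labels.

    skbio's newick writer emits the ``support`` attribute as (part of)
    the internal node label natively.
    """
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# PDB-format coordinates


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    occupancy: float
    altloc: str
    x: float
    y: float
    z: float

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    het: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name == "HOH"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)


@dataclass
class StructureModel:
    """First model of a coordinate file, altlocs resolved."""

    structure_id: str
    residues: list[Residue]

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain not in seen:
                seen.append(res.chain)
        return seen

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.het and not r.is_water]

    def het_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.het and not r.is_water]


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # keep highest occupancy per atom name; ties -> alphabetically first altloc
    by_name: dict[str, Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None or (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_rank(altloc: str) -> float:
    # higher is preferred; blank altloc ranks above any letter, then reverse
    # alphabetical so that max() picks the alphabetically first id on ties
    if altloc == "":
        return math.inf
    return -ord(altloc)


def read_structure(path: str | Path) -> StructureModel:
    """Parse PDB-format text, keeping the first model only.

    Alternative locations are resolved to the highest-occupancy copy
    (ties go to the alphabetically first altloc id).  Hydrogens are kept
    but flagged; waters are flagged via ``Residue.is_water``.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models in structure")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    occupancy=float(a.occ),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                )
                for a in res
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    het=res.het_flag == "H",
                    atoms=_resolve_altlocs(atoms),
                )
            )
    if not residues:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(structure_id=path.stem, residues=residues)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal PDB-format text."""
    lines = []
    serial = 0
    for res in model.residues:
        record = "HETATM" if res.het or res.is_water else "ATOM"
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} "
                f"{res.chain:1s}{res.number:>4d}{res.icode or '':1s}   "
                f"{atom.x:>8.3f}{atom.y:>8.3f}{atom.z:>8.3f}"
                f"{atom.occupancy:>6.2f}{0.0:>6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV tables

KINETICS_COLUMNS = [
    "enzyme_id",
    "subfamily",
    "substrate",
    "cofactor",
    "kcat_per_s",
    "km_uM",
    "kcat_over_km_per_M_per_s",
]

STRUCTURE_ANNOTATION_COLUMNS = [
    "pdb_id",
    "protein_id",
    "ligand_codes",
    "cofactor_code",
    "cofactor_redox",
    "ligand_redox",
]


def _optional_float(value, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    val = float(value)
    if val < 0:
        raise FormatError(f"row {row}: negative value {val} in column {column!r}")
    return val


def read_table(path: str | Path, schema: str):
    """Read a CSV table under one of the two supported schemas.

    ``schema="kinetics"`` yields :class:`~subfamkit.kinetics.KineticRecord`
    rows; ``schema="structure_annotations"`` yields
    :class:`~subfamkit.structure.StructureAnnotation` rows.
    """
    if schema == "kinetics":
        required = KINETICS_COLUMNS
    elif schema == "structure_annotations":
        required = STRUCTURE_ANNOTATION_COLUMNS
    else:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        if schema == "kinetics":
            out.append(
                KineticRecord(
                    enzyme_id=row["enzyme_id"],
                    subfamily=row["subfamily"] or None,
                    substrate=row["substrate"],
                    cofactor=row["cofactor"] or "unknown",
                    kcat=_optional_float(row["kcat_per_s"], "kcat_per_s", i),
                    km_uM=_optional_float(row["km_uM"], "km_uM", i),
                    efficiency=_optional_float(
                        row["kcat_over_km_per_M_per_s"], "kcat_over_km_per_M_per_s", i
                    ),
                    k_half=row.get("k_half", "").lower() in ("1", "true", "yes"),
                    source=row.get("source") or None,
                )
            )
        else:
            codes = [c.strip() for c in row["ligand_codes"].split(";") if c.strip()]
            out.append(
                StructureAnnotation(
                    pdb_id=row["pdb_id"],
                    protein_id=row["protein_id"],
                    ligand_codes=tuple(codes),
                    cofactor_code=row["cofactor_code"] or None,
                    cofactor_redox=row["cofactor_redox"] or None,
                    ligand_redox=row["ligand_redox"] or None,
                )
            )
    return out
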