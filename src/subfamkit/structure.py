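"""Active-site analysis of coordinate models.

Splits bound het groups into cofactors, crystallization additives and
candidate substrates; maps protein residues whose heavy atoms lie within
a cutoff radius (default 5 A) of the bound substrate; classifies the
complex state (apo / binary / ternary / true ternary, the last requiring
matched redox states of cofactor and substrate); and projects contacts
onto named sequence regions in reference numbering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

#: nicotinamide-cofactor het codes (NAD(H) and NADP(H) redox forms)
COFACTOR_CODES = frozenset({"NAD", "NAI", "NAJ", "NAP", "NDP", "TAP"})

#: waters, cryo-protectants and buffer ions excluded from substrate candidates
DEFAULT_EXCLUDE = frozenset(
    {"HOH", "SO4", "PO4", "GOL", "EDO", "CL", "NA", "MG", "K", "ZN"}
)

#: redox state of common cofactor and ligand het codes
DEFAULT_REDOX = {
    "NAD": "oxidized",
    "NAI": "reduced",
    "NAJ": "reduced",
    "NAP": "oxidized",
    "NDP": "reduced",
    "TAP": "oxidized",
    "LAC": "reduced",  # lactate
    "PYR": "oxidized",  # pyruvate
    "GLV": "oxidized",  # glyoxylate
    "FMT": "reduced",  # formate
    "AKG": "oxidized",  # 2-ketoglutarate
    "OAA": "oxidized",  # oxaloacetate
    "GOL3": "n/a",
}


@dataclass(frozen=True)
class StructureAnnotation:
    """One row of a curated structure-annotation table."""

    pdb_id: str
    protein_id: str
    ligand_codes: tuple[str, ...]
    cofactor_code: str | None
    cofactor_redox: str | None
    ligand_redox: str | None


@dataclass(frozen=True)
class Contact:
    chain: str
    number: int
    icode: str
    name: str
    min_distance: float
    other_subunit: bool


@dataclass
class ContactMap:
    structure_id: str
    ligand: tuple[str, str, int]  # (chain, residue name, residue number)
    contacts: list[Contact]
    radius: float

    def residue_keys(self) -> set[tuple[str, int, str]]:
        return {(c.chain, c.number, c.icode) for c in self.contacts}


@dataclass
class LigandClassification:
    cofactors: list = field(default_factory=list)
    substrates: list = field(default_factory=list)
    excluded: list = field(default_factory=list)


@dataclass
class ComplexState:
    state: str  # apo | binary | ternary | true_ternary
    cofactor: str | None = None
    substrates: tuple[str, ...] = ()
    note: str = ""


def classify_ligands(model, cofactor_codes=COFACTOR_CODES, exclude=DEFAULT_EXCLUDE):
    """Split het residues into cofactors, candidate substrates and excluded."""
    result = LigandClassification()
    for res in model.residues:
        if not res.het and not res.is_water:
            continue
        if res.is_water or res.name in exclude:
            result.excluded.append(res)
        elif res.name in cofactor_codes:
            result.cofactors.append(res)
        else:
            result.substrates.append(res)
    return result


def substrate_contacts(model, ligand, radius: float = 5.0) -> ContactMap:
    """Map protein residues within ``radius`` A of the bound ligand.

    A residue is a contact iff any of its heavy atoms lies <= radius from
    any ligand heavy atom; hydrogens are ignored on both sides.  Contacts
    contributed by a chain other than the ligand's are flagged as coming
    from another subunit.
    """
    lig_heavy = ligand.heavy_atoms()
    if not lig_heavy:
        raise ValueError(f"ligand {ligand.name} {ligand.number} has no heavy atoms")
    lig_xyz = np.array([[a.x, a.y, a.z] for a in lig_heavy])
    contacts = []
    for res in model.polymer_residues():
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        xyz = np.array([[a.x, a.y, a.z] for a in heavy])
        dmin = float(cdist(xyz, lig_xyz).min())
        if dmin <= radius:
            contacts.append(
                Contact(
                    chain=res.chain,
                    number=res.number,
                    icode=res.icode,
                    name=res.name,
                    min_distance=dmin,
                    other_subunit=res.chain != ligand.chain,
                )
            )
    return ContactMap(
        structure_id=model.structure_id,
        ligand=(ligand.chain, ligand.name, ligand.number),
        contacts=contacts,
        radius=radius,
    )


def complex_state(classification: LigandClassification, redox_table=None) -> ComplexState:
    """Classify a model's complex state from its ligand classification.

    true_ternary requires a cofactor-substrate pair in matched redox
    states (reduced+reduced or oxidized+oxidized); unknown redox codes
    yield a plain ternary with a "redox unknown" note, never true_ternary.
    """
    redox_table = DEFAULT_REDOX if redox_table is None else redox_table
    cofactors = classification.cofactors
    substrates = classification.substrates
    if not cofactors and not substrates:
        return ComplexState(state="apo")
    if cofactors and not substrates:
        return ComplexState(state="binary", cofactor=cofactors[0].name)
    cof = cofactors[0] if cofactors else None
    sub_names = tuple(s.name for s in substrates)
    if cof is None:
        return ComplexState(state="ternary", substrates=sub_names, note="no cofactor bound")
    unknown = False
    for sub in substrates:
        cr = redox_table.get(cof.name)
        sr = redox_table.get(sub.name)
        if cr is None or sr is None:
            unknown = True
            continue
        if cr in ("reduced", "oxidized") and cr == sr:
            return ComplexState(
                state="true_ternary",
                cofactor=cof.name,
                substrates=sub_names,
                note=f"{cr} cofactor with {sr} substrate",
            )
    note = "redox unknown" if unknown else "redox states mismatched"
    return ComplexState(state="ternary", cofactor=cof.name, substrates=sub_names, note=note)


def annotation_state(row: StructureAnnotation, cofactor_codes=COFACTOR_CODES,
                     exclude=DEFAULT_EXCLUDE) -> str:
    """Complex state from a curated annotation-table row (no coordinates)."""
    has_cof = bool(row.cofactor_code)
    ligands = [c for c in row.ligand_codes if c not in exclude and c not in cofactor_codes]
    if not has_cof and not ligands:
        return "apo"
    if has_cof and not ligands:
        return "binary"
    if not has_cof:
        return "ternary"
    cr, sr = row.cofactor_redox, row.ligand_redox
    if cr in ("reduced", "oxidized") and cr == sr:
        return "true_ternary"
    return "ternary"


def annotation_tallies(rows: list[StructureAnnotation], **kwargs) -> dict:
    """Tally apo/binary/ternary/true-ternary over an annotation table.

    ``n_ternary`` counts all cofactor+ligand complexes (true ternary
    included), matching the convention of reporting "structures solved
    with both a cofactor and a ligand bound".
    """
    counts = Counter(annotation_state(r, **kwargs) for r in rows)
    return {
        "n_structures": len(rows),
        "n_apo": counts["apo"],
        "n_binary": counts["binary"],
        "n_ternary": counts["ternary"] + counts["true_ternary"],
        "n_true_ternary": counts["true_ternary"],
    }


def contacts_to_regions(cmap: ContactMap, aln, refmap, regions, chain_to_row: dict) -> dict:
    """Project a contact map onto named sequence regions.

    Structure residue numbers are taken as 1-based positions in the
    ungapped sequence of the alignment row mapped to each chain; they are
    translated to reference numbering through the alignment.  Contacts
    from a subunit other than the ligand's are reported under primed
    region names; residues that cannot be mapped are listed separately.
    """
    per_region: Counter = Counter()
    unmapped = []
    for contact in cmap.contacts:
        row_id = chain_to_row.get(contact.chain)
        refpos = None
        if row_id is not None:
            col = aln.position_to_column(row_id, contact.number)
            if col is not None:
                refpos = refmap.column_to_residue(col)
        if refpos is None:
            unmapped.append(contact)
            continue
        region = regions.region_of(refpos) or "outside named regions"
        if contact.other_subunit:
            region = region + "'"
        per_region[region] += 1
    return {"per_region": dict(per_region), "unmapped": unmapped}
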