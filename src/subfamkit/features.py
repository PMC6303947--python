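"""Sequence-level functional annotation in reference numbering.

Motif search over patterns with X wildcards and bracketed residue
classes; cofactor-preference calls from the adenine-pocket loop (a
conserved aspartate marks NAD(H) preference, the [ST]R[ST]X[RK]
fingerprint marks NADP(H) preference); catalytic-triad checks with the
known natural substitutions; and scans for residues conserved above a
threshold.  Reference positions follow the GHRB representative
Q92LZ4_RHIME (PDB 5v7n): catalytic triad Arg230 / Glu259 / His277,
pyrophosphate-binding GXXGXGXXG at 146-154.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import AA20, GAP, SequenceRecord
from .msa import ConservationProfile, ReferenceMap

#: NADP(H)-specificity fingerprint of the adenine/ribose pocket loop
NADPH_FINGERPRINT = "[ST]R[ST]X[RK]"

#: pyrophosphate-binding glycine-rich motif of Rossmann-fold proteins
PYROPHOSPHATE_MOTIF = "GXXGXGXXG"

CATALYTIC_TRIAD = {230: "R", 259: "E", 277: "H"}
AUXILIARY_POSITIONS = {72: "V", 73: "G", 195: "D", 227: "N", 229: "G", 231: "G"}

#: documented natural substitutions at checked positions
KNOWN_SUBSTITUTIONS = {
    (259, "Q"): "FDH-like",
    (277, "K"): "SERA-IIIK-like",
    (277, "W"): "X4-like, catalysis questionable",
    (195, "R"): "structural-arginine variant",
    (72, "A"): "small-residue variant",
    (72, "S"): "small-residue variant",
    (72, "T"): "small-residue variant",
}


class MotifError(ValueError):
    """Malformed motif pattern."""


@dataclass(frozen=True)
class MotifPattern:
    """Pattern over residue letters, X wildcards and bracketed classes."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        self.positions()  # validates

    def positions(self) -> list[str]:
        """Split the pattern into per-position tokens; raises on malformed input."""
        tokens = []
        i = 0
        pat = self.pattern
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                end = pat.find("]", i)
                if end == -1:
                    raise MotifError(f"unclosed '[' at offset {i}")
                inner = pat[i + 1 : end]
                if not inner or not set(inner) <= set(AA20):
                    raise MotifError(f"invalid residue class {pat[i:end + 1]!r} at offset {i}")
                tokens.append(inner)
                i = end + 1
            elif ch == "X":
                tokens.append(AA20)
                i += 1
            elif ch in AA20:
                tokens.append(ch)
                i += 1
            else:
                raise MotifError(f"invalid pattern character {ch!r} at offset {i}")
        if len(tokens) < 2:
            raise MotifError("pattern must span at least 2 positions")
        return tokens

    def to_regex(self) -> re.Pattern:
        parts = []
        for tok in self.positions():
            if len(tok) == 1:
                parts.append(tok)
            elif tok == AA20:
                parts.append(f"[{AA20}]")
            else:
                parts.append(f"[{tok}]")
        return re.compile("(?=(" + "".join(parts) + "))")

    def __len__(self) -> int:
        return len(self.positions())


def find_motif(seq: SequenceRecord | str, motif: MotifPattern | str) -> list[int]:
    """All (possibly overlapping) motif match starts, 1-based on the
    ungapped sequence; gaps in aligned rows are skipped transparently."""
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    residues = seq if isinstance(seq, str) else seq.residues
    residues = residues.replace(GAP, "")
    regex = motif.to_regex()
    return [m.start() + 1 for m in regex.finditer(residues)]


@dataclass(frozen=True)
class RegionDefinitions:
    """Named sequence regions as inclusive reference-residue intervals.

    The default boundaries are curated approximations (the underlying
    loops are named, not tabulated, in the literature); treat them as a
    configurable starting point, not ground truth.
    """

    regions: dict[str, tuple[int, int]]
    #: reference position of the cofactor-discriminating aspartate
    key_cofactor_position: int = 180
    approximate: bool = True

    def __post_init__(self) -> None:
        names = list(self.regions)
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for name, (start, end) in self.regions.items():
            if start < 1 or end < start:
                raise ValueError(f"region {name!r}: bad interval [{start}, {end}]")

    @classmethod
    def default(cls) -> "RegionDefinitions":
        return cls(
            regions={
                "b1-a1": (10, 18),
                "b3-a3": (52, 60),
                "b4-a4": (70, 78),
                "a5": (100, 115),
                "b5-aA": (120, 130),
                "bB-aD": (175, 185),
                "bG-a5": (285, 295),
                "aB'-bA'": (300, 312),
                "PDXB-dim": (316, 330),
            },
            key_cofactor_position=180,
        )

    def region_of(self, residue: int) -> str | None:
        for name, (start, end) in self.regions.items():
            if start <= residue <= end:
                return name
        return None

    @classmethod
    def from_toml(cls, path) -> "RegionDefinitions":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(
            regions={k: tuple(v) for k, v in data["regions"].items()},
            key_cofactor_position=data.get("key_cofactor_position", 180),
            approximate=data.get("approximate", True),
        )


@dataclass(frozen=True)
class CofactorCall:
    call: str  # "NADH" | "NADPH" | "ambiguous"
    evidence: str
    conflict: bool = False


def cofactor_preference(row: SequenceRecord, regions: RegionDefinitions,
                        refmap: ReferenceMap) -> CofactorCall:
    """Call cofactor preference from the adenine-pocket loop.

    NADH when the key loop position carries aspartate; NADPH when the
    [ST]R[ST]X[RK] fingerprint matches inside the loop; ambiguous when
    neither, or both (the latter flagged as a conflict).
    """
    name = "bB-aD"
    if name not in regions.regions:
        raise ValueError("region definitions lack the cofactor loop (bB-aD)")
    start, end = regions.regions[name]
    cols = sorted(c for c, r in refmap.col_to_res.items() if start <= r <= end)
    if not cols:
        return CofactorCall("ambiguous", "no-coverage: loop unmapped in alignment")
    segment = "".join(row.residues[c] for c in cols)
    ungapped = segment.replace(GAP, "")
    if not ungapped:
        return CofactorCall("ambiguous", "no-coverage: loop entirely gapped")
    key_col = refmap.residue_to_column(regions.key_cofactor_position)
    key_res = row.residues[key_col] if key_col is not None else None
    nadh = key_res == "D"
    nadph = bool(MotifPattern(NADPH_FINGERPRINT).to_regex().search(ungapped))
    if nadh and nadph:
        return CofactorCall(
            "ambiguous",
            f"conflict: aspartate at {regions.key_cofactor_position} AND "
            f"{NADPH_FINGERPRINT} in loop",
            conflict=True,
        )
    if nadh:
        return CofactorCall("NADH", f"aspartate at position {regions.key_cofactor_position}")
    if nadph:
        return CofactorCall("NADPH", f"{NADPH_FINGERPRINT} fingerprint in loop")
    return CofactorCall("ambiguous", "neither aspartate nor fingerprint found")


@dataclass(frozen=True)
class PositionReport:
    position: int
    expected: str
    observed: str  # residue letter or "-" for gap
    canonical: bool
    label: str | None  # known-substitution label, "non-canonical", "gap" or None


@dataclass(frozen=True)
class TriadReport:
    entries: tuple[PositionReport, ...]

    def at(self, position: int) -> PositionReport:
        for entry in self.entries:
            if entry.position == position:
                return entry
        raise KeyError(position)

    @property
    def all_canonical(self) -> bool:
        return all(e.canonical for e in self.entries if e.position in CATALYTIC_TRIAD)


def triad_check(row: SequenceRecord, refmap: ReferenceMap) -> TriadReport:
    """Check the catalytic triad (and auxiliary positions) of one row.

    Canonical residues are Arg230 / Glu259 / His277; the documented
    natural substitutions (Glu259Gln in formate dehydrogenases,
    His277Lys and His277Trp) get their own labels; anything else is
    "non-canonical".  Exactly one entry (and at most one label) per
    queried position; gapped positions report "-".
    """
    entries = []
    for position, expected in {**CATALYTIC_TRIAD, **AUXILIARY_POSITIONS}.items():
        col = refmap.residue_to_column(position)
        observed = row.residues[col] if col is not None else GAP
        if observed == GAP:
            entries.append(PositionReport(position, expected, GAP, False, "gap"))
            continue
        if observed == expected:
            entries.append(PositionReport(position, expected, observed, True, None))
            continue
        label = KNOWN_SUBSTITUTIONS.get((position, observed), "non-canonical")
        entries.append(PositionReport(position, expected, observed, False, label))
    return TriadReport(tuple(sorted(entries, key=lambda e: e.position)))


def conserved_scan(profile: ConservationProfile, threshold: float = 0.9,
                   refmap: ReferenceMap | None = None) -> list[tuple]:
    """Columns whose modal residue exceeds ``threshold`` (strictly).

    Returns (column, residue, frequency[, reference position]) tuples;
    fully gapped columns never qualify (their modal frequency is 0).
    """
    out = []
    for col in range(len(profile)):
        residue = profile.modal_residue[col]
        freq = float(profile.modal_frequency[col])
        if residue is None or freq <= threshold:
            continue
        if refmap is not None:
            out.append((col, residue, freq, refmap.column_to_residue(col)))
        else:
            out.append((col, residue, freq))
    return out
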