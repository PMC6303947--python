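"""Multiple-alignment operations.

The Alignment container is a rectangular set of gapped SequenceRecords.
Operations: length-preserving extension of a seed alignment by
sequence-to-profile alignment (insertions relative to the seed are
dropped and logged), gap-fraction column trimming, per-column
conservation statistics, subfamily sequence-logo matrices, and mapping
of alignment columns to the numbering of a reference row.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AA20, GAP, SequenceRecord
from .pairwise import _INDEX, ScoringScheme


@dataclass(frozen=True)
class Alignment:
    """Rectangular gapped alignment with unique row ids."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {', '.join(dupes)}")

    @classmethod
    def from_records(cls, records) -> "Alignment":
        return cls(tuple(records))

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, row_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == row_id:
                return rec
        raise KeyError(row_id)

    def to_array(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])

    def position_to_column(self, row_id: str, position: int) -> int | None:
        """Alignment column of the ``position``-th (1-based) residue of a row."""
        seen = 0
        for col, ch in enumerate(self.row(row_id).residues):
            if ch != GAP:
                seen += 1
                if seen == position:
                    return col
        return None


@dataclass(frozen=True)
class ReferenceMap:
    """Alignment column <-> reference residue number (1-based, ungapped)."""

    ref_id: str
    col_to_res: dict[int, int]

    def column_to_residue(self, col: int) -> int | None:
        return self.col_to_res.get(col)

    def residue_to_column(self, residue: int) -> int | None:
        for col, res in self.col_to_res.items():
            if res == residue:
                return col
        return None

    @property
    def n_mapped(self) -> int:
        return len(self.col_to_res)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column modal residue, modal frequency, gap fraction, information."""

    modal_residue: tuple[str | None, ...]
    modal_frequency: np.ndarray  # fraction of ALL rows (gaps count against)
    gap_fraction: np.ndarray
    information: np.ndarray  # bits, over non-gap rows

    def __len__(self) -> int:
        return len(self.modal_residue)


def add_to_seed(seed: Alignment, new_seqs: list[SequenceRecord],
                s: ScoringScheme | None = None):
    """Align new sequences independently to the seed profile.

    Seed columns are never changed: each new sequence is threaded onto
    the fixed column grid (profile column score = mean substitution score
    against the column's residues; gaps scored as gap-extend).  Residues
    falling in insertions relative to the seed are dropped and reported
    in the returned log, keyed by sequence id.
    """
    s = s or ScoringScheme()
    collisions = sorted(set(seed.ids) & {r.id for r in new_seqs})
    if collisions:
        raise ValueError(f"new sequence ids collide with seed rows: {', '.join(collisions)}")
    L = seed.length
    ge = s.gap_extend
    # profile[j, r] = mean substitution score of residue r against column j
    arr = seed.to_array()
    n_letters = s.matrix.shape[0]
    profile = np.full((L, n_letters), -ge)
    for j in range(L):
        col = [c for c in arr[:, j] if c != GAP]
        if col:
            idx = [_INDEX[c] for c in col]
            profile[j] = s.matrix[:, idx].mean(axis=1)
    rows = list(seed.records)
    dropped_log: dict[str, list[int]] = {}
    for seq in new_seqs:
        residues = seq.ungapped()
        gapped, dropped = _thread_to_profile(residues, profile, ge)
        rows.append(SequenceRecord(seq.id, gapped, seq.description))
        if dropped:
            dropped_log[seq.id] = dropped
    return Alignment.from_records(rows), dropped_log


def _thread_to_profile(residues: str, profile: np.ndarray, ge: float):
    """NW threading of a sequence onto fixed profile columns (linear gaps)."""
    n, L = len(residues), profile.shape[0]
    enc = [_INDEX[c] for c in residues]
    S = np.zeros((n + 1, L + 1))
    S[1:, 0] = -ge * np.arange(1, n + 1)  # dropped prefix residues
    S[0, 1:] = -ge * np.arange(1, L + 1)  # leading gap columns
    ptr = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0 diag, 1 drop residue, 2 gap col
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        match = S[i - 1, :-1] + profile[:, enc[i - 1]]
        for j in range(1, L + 1):
            diag = match[j - 1]
            drop = S[i - 1, j] - ge
            gap = S[i, j - 1] - ge
            # deterministic preference: diagonal, then drop (up), then gap (left)
            if diag >= drop and diag >= gap:
                S[i, j], ptr[i, j] = diag, 0
            elif drop >= gap:
                S[i, j], ptr[i, j] = drop, 1
            else:
                S[i, j], ptr[i, j] = gap, 2
    out = []
    dropped = []
    i, j = n, L
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            out.append(residues[i - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            dropped.append(i)  # 1-based position on the ungapped sequence
            i -= 1
        else:
            out.append(GAP)
            j -= 1
    out.reverse()
    dropped.reverse()
    return "".join(out), dropped


def trim_columns(aln: Alignment, max_gap_fraction: float = 0.8):
    """Remove columns whose gap fraction is >= ``max_gap_fraction``.

    Returns the trimmed alignment plus the removed column indices in
    input coordinates.  Row order is preserved; idempotent.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    arr = aln.to_array()
    gap_frac = (arr == GAP).mean(axis=0)
    removed = [int(j) for j in np.where(gap_frac >= max_gap_fraction)[0]]
    if len(removed) == aln.length:
        raise ValueError("trimming would remove every column")
    keep = [j for j in range(aln.length) if gap_frac[j] < max_gap_fraction]
    rows = [
        SequenceRecord(r.id, "".join(r.residues[j] for j in keep), r.description)
        for r in aln.records
    ]
    return Alignment.from_records(rows), removed


MAX_INFORMATION = math.log2(20)


def conservation(aln: Alignment) -> ConservationProfile:
    """Per-column conservation statistics.

    Modal frequency uses all rows in the denominator (gaps count against
    conservation).  Information content is log2(20) minus the Shannon
    entropy of residue frequencies renormalized over non-gap rows; fully
    gapped columns get 0 bits and no modal residue.
    """
    arr = aln.to_array()
    n = aln.n_rows
    modal_res: list[str | None] = []
    modal_freq = np.zeros(aln.length)
    gap_frac = np.zeros(aln.length)
    info = np.zeros(aln.length)
    for j in range(aln.length):
        col = arr[:, j]
        residues = [c for c in col if c != GAP]
        gap_frac[j] = 1.0 - len(residues) / n
        if not residues:
            modal_res.append(None)
            continue
        counts = Counter(residues)
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        modal_res.append(best[0])
        modal_freq[j] = best[1] / n
        freqs = np.array(list(counts.values()), dtype=float)
        freqs /= freqs.sum()
        entropy = float(-(freqs * np.log2(freqs)).sum())
        info[j] = max(0.0, MAX_INFORMATION - entropy)
    return ConservationProfile(tuple(modal_res), modal_freq, gap_frac, info)


def logo_columns(aln: Alignment, partition, min_nongap: float = 0.9):
    """Columns and per-subfamily frequency matrices for sequence logos.

    A column is included iff in at least one subfamily at least
    ``min_nongap`` of the members carry a residue there.  Frequencies
    are normalized per included column within each subfamily (columns
    where a subfamily is fully gapped stay all-zero).
    """
    arr = aln.to_array()
    id_to_row = {rid: k for k, rid in enumerate(aln.ids)}
    groups: dict[str, list[int]] = {}
    for name, members in partition.subfamilies.items():
        if not members:
            raise ValueError(f"subfamily {name!r} has no members")
        missing = sorted(set(members) - set(id_to_row))
        if missing:
            raise ValueError(f"subfamily {name!r} members absent from alignment: {missing}")
        groups[name] = [id_to_row[m] for m in members]
    included = []
    for j in range(aln.length):
        for rows in groups.values():
            col = arr[rows, j]
            if (col != GAP).mean() >= min_nongap:
                included.append(j)
                break
    matrices = {}
    letters = list(AA20)
    for name, rows in groups.items():
        freq = np.zeros((len(included), 20))
        for k, j in enumerate(included):
            col = [c for c in arr[rows, j] if c != GAP and c != "X"]
            if not col:
                continue
            counts = Counter(col)
            total = sum(counts.values())
            for li, letter in enumerate(letters):
                freq[k, li] = counts.get(letter, 0) / total
        matrices[name] = pd.DataFrame(freq, index=included, columns=letters)
    return included, matrices


def reference_numbering(aln: Alignment, ref_id: str) -> ReferenceMap:
    """Map alignment columns to 1-based residue numbers of a reference row."""
    ref = aln.row(ref_id)  # KeyError if absent
    mapping = {}
    number = 0
    for col, ch in enumerate(ref.residues):
        if ch != GAP:
            number += 1
            mapping[col] = number
    return ReferenceMap(ref_id=ref_id, col_to_res=mapping)
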