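"""Synthetic-data generators giving every pipeline stage ground truth.

simulate_family plants a known subfamily structure: a star of subfamily
stems (long branches separating the groups), each carrying a random
binary tree over its leaves (short within-group branches), and evolves
sequences site-wise under a 20-state uniform-exchange Poisson process.
Invariant columns (e.g. catalytic positions) are never substituted;
subfamily-specific motif instances are written at each subfamily root
and held fixed within that subfamily, emulating conserved functional
fingerprints.  No indels are simulated by default, so the true alignment
is the ungapped identity; an optional gap-injection mode exercises
column trimming.

simulate_kinetics and simulate_complex produce toy kinetics tables and
toy active-site coordinate sets with known summary statistics and known
contact lists.

Under the uniform-exchange process (rate 1 substitution/site, each event
replacing the residue with one of the other 19 uniformly), the chance
that a site differs between two sequences separated by total path length
t is p(t) = (19/20) * (1 - exp(-(20/19) t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from .io import AA20, GAP, Atom, Residue, SequenceRecord, StructureModel
from .kinetics import KineticRecord
from .msa import Alignment
from .structure import Contact, ContactMap

N_STATES = 20


@dataclass(frozen=True)
class MotifInjection:
    """A motif instance written into a subfamily's sequences."""

    subfamily: int  # 0-based subfamily index
    start_column: int  # 0-based
    instance: str  # concrete residue string, e.g. "TRSAK"


@dataclass(frozen=True)
class FamilySpec:
    """Planted-family parameters.

    Defaults are the reference conditions used throughout the test
    suite: 6 subfamilies x 8 leaves, 300 columns, within-subfamily
    branch scale 0.05 substitutions/site and stem scale 0.8, which give
    clearly separated, fully recoverable subfamilies.
    """

    n_subfamilies: int = 6
    leaves_per_subfamily: int = 8
    length: int = 300
    within_scale: float = 0.05
    stem_scale: float = 0.8
    invariant_columns: dict[int, str] = field(default_factory=dict)
    motif_injections: tuple[MotifInjection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies * self.leaves_per_subfamily < 4:
            raise ValueError("need at least 4 leaves in total")
        if self.n_subfamilies < 2:
            raise ValueError("need at least 2 subfamilies")
        if self.within_scale <= 0 or self.stem_scale <= 0:
            raise ValueError("branch scales must be positive")
        motif_cols: set[int] = set()
        for inj in self.motif_injections:
            if inj.subfamily >= self.n_subfamilies:
                raise ValueError(f"motif injection names subfamily {inj.subfamily}, "
                                 f"but only {self.n_subfamilies} exist")
            cols = range(inj.start_column, inj.start_column + len(inj.instance))
            if cols.stop > self.length:
                raise ValueError("motif extends past the sequence length")
            if not set(inj.instance) <= set(AA20):
                raise ValueError(f"motif instance {inj.instance!r} has invalid residues")
            motif_cols |= set(cols)
        bad = motif_cols & set(self.invariant_columns)
        if bad:
            raise ValueError(f"invariant and motif columns overlap: {sorted(bad)}")
        for col, res in self.invariant_columns.items():
            if not 0 <= col < self.length:
                raise ValueError(f"invariant column {col} out of range")
            if res not in AA20:
                raise ValueError(f"invariant residue {res!r} invalid")


@dataclass
class SimulatedFamily:
    tree: TreeNode
    alignment: Alignment  # ungapped sequences of equal length
    truth: dict[str, str]  # leaf id -> subfamily name ("SF1"..)
    spec: FamilySpec


def _p_same(t: float) -> float:
    return 1.0 / N_STATES + (N_STATES - 1) / N_STATES * math.exp(-N_STATES / (N_STATES - 1) * t)


def expected_p_distance(t: float) -> float:
    """Exact expected proportion of differing sites at path length t."""
    return 1.0 - _p_same(t)


def _evolve(seq: np.ndarray, t: float, frozen: np.ndarray, rng) -> np.ndarray:
    """One branch of the uniform-exchange process (exact transition sampling)."""
    out = seq.copy()
    p_change = 1.0 - _p_same(t)
    mutate = (~frozen) & (rng.random(len(seq)) < p_change)
    idx = np.where(mutate)[0]
    if len(idx):
        # uniform among the 19 alternatives
        shift = rng.integers(1, N_STATES, size=len(idx))
        out[idx] = (out[idx] + shift) % N_STATES
    return out


def _random_binary_subtree(leaf_names: list[str], scale: float, rng) -> TreeNode:
    nodes = [TreeNode(name=n) for n in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode()
        a.length = float(rng.exponential(scale))
        b.length = float(rng.exponential(scale))
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def simulate_family(spec: FamilySpec) -> SimulatedFamily:
    """Generate a planted family: true tree, sequences and truth map."""
    rng = np.random.default_rng(spec.seed)
    root = TreeNode()
    root.length = 0.0
    truth: dict[str, str] = {}
    for k in range(spec.n_subfamilies):
        names = [f"SF{k + 1}_L{i + 1}" for i in range(spec.leaves_per_subfamily)]
        for n in names:
            truth[n] = f"SF{k + 1}"
        if len(names) == 1:
            sub = TreeNode(name=names[0])
        else:
            sub = _random_binary_subtree(names, spec.within_scale, rng)
        sub.length = spec.stem_scale
        root.append(sub)

    letters = np.frombuffer(AA20.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, N_STATES, size=spec.length)
    frozen_base = np.zeros(spec.length, dtype=bool)
    for col, res in spec.invariant_columns.items():
        root_seq[col] = AA20.index(res)
        frozen_base[col] = True

    sequences: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray, frozen: np.ndarray, sf_index: int | None):
        for child in node.children:
            child_frozen = frozen
            child_sf = sf_index
            child_seq = seq
            if sf_index is None:
                # crossing into a subfamily stem: inject motifs, then evolve
                child_sf = node.children.index(child)
                child_frozen = frozen.copy()
                child_seq = seq.copy()
                for inj in spec.motif_injections:
                    if inj.subfamily == child_sf:
                        for off, res in enumerate(inj.instance):
                            col = inj.start_column + off
                            child_seq[col] = AA20.index(res)
                            child_frozen[col] = True
            evolved = _evolve(child_seq, child.length or 0.0, child_frozen, rng)
            if child.is_tip():
                sequences[child.name] = evolved
            else:
                descend(child, evolved, child_frozen, child_sf)

    descend(root, root_seq, frozen_base, None)
    records = [
        SequenceRecord(name, letters[sequences[name]].tobytes().decode())
        for name in sorted(sequences)
    ]
    return SimulatedFamily(
        tree=root,
        alignment=Alignment.from_records(records),
        truth=truth,
        spec=spec,
    )


def inject_gaps(aln: Alignment, n_columns: int, gap_fraction: float, seed: int = 0) -> Alignment:
    """Turn ``n_columns`` random columns mostly to gaps (to exercise trimming)."""
    rng = np.random.default_rng(seed)
    cols = rng.choice(aln.length, size=n_columns, replace=False)
    arr = aln.to_array()
    for col in cols:
        rows = rng.random(aln.n_rows) < gap_fraction
        arr[rows, col] = GAP
    return Alignment.from_records(
        SequenceRecord(rec.id, "".join(arr[i]), rec.description)
        for i, rec in enumerate(aln.records)
    )


def simulate_kinetics(truth: dict[str, str],
                      law: dict[tuple[str, str], tuple[float | None, float]],
                      seed: int = 0, km_median_uM: float = 600.0,
                      km_sigma: float = 0.5) -> list[KineticRecord]:
    """Toy kinetics table with known medians and counts by construction.

    ``law`` maps (subfamily, substrate) to (median efficiency, lognormal
    sigma); a ``None`` median plants a record without efficiency (KM
    only).  Efficiencies are lognormal around the planted median, so a
    point-mass law (sigma 0) reproduces its median exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for enzyme in sorted(truth):
        subfamily = truth[enzyme]
        for (sf, substrate), (median, sigma) in sorted(law.items()):
            if sf != subfamily:
                continue
            km = float(km_median_uM * math.exp(km_sigma * rng.standard_normal()))
            if median is None:
                records.append(KineticRecord(
                    enzyme_id=enzyme, substrate=substrate, subfamily=subfamily,
                    cofactor="NADH", km_uM=km))
                continue
            eff = float(median * math.exp(sigma * rng.standard_normal()))
            records.append(KineticRecord(
                enzyme_id=enzyme, substrate=substrate, subfamily=subfamily,
                cofactor="NADH", kcat=eff * km * 1e-6, km_uM=km, efficiency=eff))
    return records


def _random_unit_vectors(n: int, rng) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_complex(n_contacts: int, radius: float = 5.0, seed: int = 0,
                     n_noncontacts: int | None = None,
                     include_boundary: bool = True) -> tuple[StructureModel, ContactMap]:
    """A toy active site with a known contact list.

    One ligand heavy atom sits at the origin; ``n_contacts`` protein
    residues are placed at controlled distances <= radius (one exactly
    at the radius when ``include_boundary``), and as many non-contacts
    just outside it.  Each residue also carries a hydrogen closer than
    its heavy atom, which a correct contact mapper must ignore.
    Returns the model together with the expected contact map.
    """
    if n_contacts < 0:
        raise ValueError("n_contacts must be >= 0")
    rng = np.random.default_rng(seed)
    if n_noncontacts is None:
        n_noncontacts = n_contacts
    ligand = Residue(chain="A", number=500, icode="", name="LIG", het=True,
                     atoms=[Atom("C1", "C", 1.0, "", 0.0, 0.0, 0.0)])
    residues: list[Residue] = [ligand]
    expected: list[Contact] = []
    number = 0
    dirs = _random_unit_vectors(n_contacts + n_noncontacts, rng)
    for k in range(n_contacts):
        number += 1
        if include_boundary and k == 0:
            # axis-aligned so the distance is exactly the radius in floats
            dist = radius
            direction = np.array([1.0, 0.0, 0.0])
        else:
            dist = float(rng.uniform(1.5, radius * 0.98))
            direction = dirs[k]
        pos = direction * dist
        hpos = direction * max(dist - 1.0, 0.5)
        residues.append(Residue(
            chain="A", number=number, icode="", name="ALA", het=False,
            atoms=[Atom("CA", "C", 1.0, "", *pos), Atom("HA", "H", 1.0, "", *hpos)]))
        expected.append(Contact("A", number, "", "ALA", dist, False))
    for k in range(n_noncontacts):
        number += 1
        dist = float(rng.uniform(radius * 1.02, radius * 2.0))
        pos = dirs[n_contacts + k] * dist
        hpos = dirs[n_contacts + k] * (radius * 0.5)  # hydrogen inside the radius
        residues.append(Residue(
            chain="A", number=number, icode="", name="GLY", het=False,
            atoms=[Atom("CA", "C", 1.0, "", *pos), Atom("HA", "H", 1.0, "", *hpos)]))
    model = StructureModel(structure_id=f"synthetic-{seed}", residues=residues)
    cmap = ContactMap(structure_id=model.structure_id, ligand=("A", "LIG", 500),
                      contacts=expected, radius=radius)
    return model, cmap
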