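"""Consensus-clade subfamily extraction and query classification.

A subfamily is a group of proteins that appears as a clade with branch
support strictly above a threshold in EVERY input tree.  Candidate leaf
sets are the supported bipartition sides of each tree; the partition is
a greedy maximal-disjoint selection of candidates shared by all trees,
capped at a fraction of the full leaf set so that near-root bipartitions
are not swallowed whole.  Leaves in no selected clade (including single
long branches) stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

from .io import SequenceRecord
from .msa import Alignment
from .pairwise import ScoringScheme, evalue, local_align, percent_identity
from .phylo import bipartitions

UNASSIGNED = "UNASSIGNED"


@dataclass
class SubfamilyPartition:
    """Disjoint named leaf sets plus an unassigned pool."""

    subfamilies: dict[str, frozenset]
    unassigned: frozenset
    #: per subfamily, the minimum support observed across the input trees
    provenance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for name, members in self.subfamilies.items():
            if seen & set(members):
                raise ValueError(f"subfamily {name!r} overlaps another subfamily")
            seen |= set(members)
        if seen & set(self.unassigned):
            raise ValueError("unassigned pool overlaps a subfamily")

    @property
    def all_leaves(self) -> frozenset:
        out = set(self.unassigned)
        for members in self.subfamilies.values():
            out |= members
        return frozenset(out)

    def subfamily_of(self, leaf: str) -> str:
        for name, members in self.subfamilies.items():
            if leaf in members:
                return name
        return UNASSIGNED

    def labels(self) -> dict[str, str]:
        return {leaf: self.subfamily_of(leaf) for leaf in sorted(self.all_leaves)}


def supported_clades(tree: TreeNode, min_support: float = 0.5) -> dict[frozenset, float]:
    """Leaf sets of bipartitions with support strictly above ``min_support``.

    Both sides of each qualifying internal edge are emitted (trees are
    treated as unrooted); singletons and the full leaf set are excluded.
    """
    leaves = frozenset(t.name for t in tree.tips())
    parts = bipartitions(tree)
    if not parts:  # fully unresolved star: nothing to emit
        return {}
    if not any(getattr(node, "support", None) is not None for node in parts.values()):
        raise ValueError("tree carries no support values")
    out: dict[frozenset, float] = {}
    for side, node in parts.items():
        support = getattr(node, "support", None)
        if support is None or support <= min_support:
            continue
        for clade in (side, leaves - side):
            if 2 <= len(clade) < len(leaves):
                prev = out.get(clade)
                if prev is None or support > prev:
                    out[clade] = support
    return out


def consensus_subfamilies(trees: list[TreeNode], min_support: float = 0.5,
                          min_size: int = 2, max_fraction: float = 0.5) -> SubfamilyPartition:
    """Subfamilies = clades supported above threshold in every tree.

    Candidates present in all trees are selected greedily by decreasing
    size (ties: lexicographically smallest member), skipping candidates
    that overlap an already selected clade or exceed ``max_fraction`` of
    all leaves.  Selected clades are named SF1..SFn in selection order;
    everything else is unassigned.
    """
    if len(trees) < 2:
        raise ValueError("consensus requires at least 2 trees")
    leaf_sets = [frozenset(t.name for t in tree.tips()) for tree in trees]
    for k, ls in enumerate(leaf_sets[1:], start=2):
        diff = sorted(ls ^ leaf_sets[0])
        if diff:
            raise ValueError(f"tree 1 and tree {k} differ in leaves: {', '.join(diff)}")
    leaves = leaf_sets[0]
    per_tree = [supported_clades(tree, min_support) for tree in trees]
    candidates = set(per_tree[0])
    for clades in per_tree[1:]:
        candidates &= set(clades)
    scored = {
        clade: min(clades[clade] for clades in per_tree) for clade in candidates
    }
    ordered = sorted(scored, key=lambda c: (-len(c), min(c)))
    selected: list[frozenset] = []
    taken: set = set()
    cap = max_fraction * len(leaves)
    for clade in ordered:
        if len(clade) < min_size or len(clade) > cap:
            continue
        if taken & clade:
            continue
        selected.append(clade)
        taken |= clade
    subfams = {f"SF{k + 1}": clade for k, clade in enumerate(selected)}
    return SubfamilyPartition(
        subfamilies=subfams,
        unassigned=frozenset(leaves - taken),
        provenance={name: scored[clade] for name, clade in subfams.items()},
    )


@dataclass(frozen=True)
class Assignment:
    subfamily: str  # subfamily name or UNASSIGNED
    best_hit: str | None
    identity: float | None
    evalue: float | None
    score: float | None


def assign_query(query: SequenceRecord, representatives: Alignment,
                 partition: SubfamilyPartition, s: ScoringScheme | None = None,
                 min_identity: float = 30.0, e_max: float = 1e-3) -> Assignment:
    """Classify a query sequence by its best local alignment hit.

    The best-scoring representative determines the subfamily when its
    identity is at least ``min_identity`` percent and E < ``e_max``;
    otherwise the query is unassigned (best hit still reported).
    """
    if not query.ungapped():
        raise ValueError("query sequence is empty")
    s = s or ScoringScheme()
    best = None
    for rec in representatives.records:
        rep = rec.ungap()
        aln = local_align(query, rep, s)
        if len(aln) == 0:
            continue
        e = evalue(aln.score, len(query.ungapped()), len(rep.residues), s)
        cand = (aln.score, -e, rec.id, percent_identity(aln))
        if best is None or cand > best:
            best = cand
    if best is None:
        return Assignment(UNASSIGNED, None, None, None, None)
    score, neg_e, hit_id, identity = best
    e = -neg_e
    if identity >= min_identity and e < e_max:
        return Assignment(partition.subfamily_of(hit_id), hit_id, identity, e, score)
    return Assignment(UNASSIGNED, hit_id, identity, e, score)
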