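"""Distance-based phylogenetics: p/Poisson distances, neighbor joining,
bootstrap bipartition supports and midpoint rooting.

Distances use pairwise deletion (only columns where both rows carry a
residue).  The Poisson correction is d = -ln(1 - p).  Neighbor joining
is the classic Q-criterion agglomeration with deterministic
lexicographic tie-breaking and negative branch-length estimates clamped
to zero; on additive matrices it recovers the generating tree exactly.
Bootstrap supports are the fraction of column-resampled replicate trees
containing each bipartition of the reference tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .io import GAP, SequenceRecord
from .msa import Alignment

logger = logging.getLogger(__name__)

SATURATION_P = 0.99
SATURATION_CLAMP_D = 5.0


class SaturatedPairError(ValueError):
    """A sequence pair is too diverged for the Poisson correction."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("distances must be finite and non-negative")

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])


def distance_matrix(aln: Alignment, model: str = "poisson",
                    clamp_saturated: bool = False) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``model="p"``: observed proportion of differing sites over shared
    non-gap columns.  ``model="poisson"``: -ln(1 - p).  Pairs sharing no
    columns raise; saturated pairs (p >= 0.99) raise unless
    ``clamp_saturated`` caps them at 5.0 substitutions/site.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if aln.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    arr = aln.to_array()
    nongap = arr != GAP
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no non-gap columns"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / n_shared
            if model == "p":
                d[i, j] = d[j, i] = p
                continue
            if p >= SATURATION_P:
                if not clamp_saturated:
                    raise SaturatedPairError(
                        f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) is saturated (p = {p:.3f})"
                    )
                d[i, j] = d[j, i] = SATURATION_CLAMP_D
            else:
                d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels=list(aln.ids), data=d)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; trifurcating root).

    Q-criterion joins with ties broken on the smallest lexicographic
    pair of cluster keys (a cluster's key is its lexicographically
    smallest leaf).  Negative branch-length estimates are clamped to 0
    and the total deficit logged.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = D.data.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    keys: list[str] = list(D.labels)
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0.0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        i, j = min(
            (tuple(sorted((int(a), int(b)), key=lambda k: keys[k])) for a, b in cands if a < b),
            key=lambda ij: (keys[ij[0]], keys[ij[1]]),
        )
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li), clamp(lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    # final three-point resolution
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    root = TreeNode()
    root.extend(nodes)
    root.length = 0.0
    if deficit > 0.0:
        logger.info("neighbor joining clamped negative branch lengths (deficit %.3g)", deficit)
    for node in root.traverse(include_self=True):
        node.support = None
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of an unrooted tree, keyed canonically.

    Each internal edge splits the leaves in two; the canonical key is
    the side NOT containing the lexicographically smallest leaf.
    """
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.setdefault(frozenset(side), node)
    return out


def bootstrap_supports(aln: Alignment, reference: TreeNode, n: int = 100,
                       model: str = "poisson", seed: int = 0) -> TreeNode:
    """Attach bootstrap supports to a copy of the reference tree.

    ``n`` column-resampled (with replacement, same length) alignments are
    each run through distance + NJ; the support of each internal edge of
    the reference is the fraction of successful replicate trees containing
    the same leaf-set bipartition.  Replicates hitting a saturated pair
    are skipped and counted; more than 20% skipped is an error.
    Deterministic for a given seed.
    """
    ref_leaves = {t.name for t in reference.tips()}
    if ref_leaves != set(aln.ids):
        raise ValueError("reference tree leaves do not match alignment rows")
    result = reference.copy()
    ref_parts = bipartitions(result)
    if not ref_parts:
        for node in result.traverse(include_self=True):
            node.support = None
        result.n_skipped_replicates = 0
        return result
    rng = np.random.default_rng(seed)
    counts = {part: 0 for part in ref_parts}
    skipped = 0
    arr = aln.to_array()
    for _ in range(n):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = Alignment.from_records(
            SequenceRecord(rec.id, "".join(arr[i, cols]), rec.description)
            for i, rec in enumerate(aln.records)
        )
        try:
            rep_d = distance_matrix(rep_aln, model=model)
        except SaturatedPairError:
            skipped += 1
            continue
        rep_parts = bipartitions(nj_tree(rep_d))
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    if skipped > 0.2 * n:
        raise SaturatedPairError(
            f"{skipped}/{n} bootstrap replicates skipped due to saturated pairs"
        )
    successful = n - skipped
    for node in result.traverse(include_self=True):
        node.support = None
    for part, node in ref_parts.items():
        node.support = counts[part] / successful if successful else None
    result.n_skipped_replicates = skipped
    return result


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Ties on the longest path are broken by the lexicographically
    smallest (sorted) leaf pair.  All-zero branch lengths are an error.
    Leaf-to-leaf path lengths are preserved by the re-rooting.
    """
    work = tree.copy()
    tips = list(work.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    dm = work.tip_tip_distances()
    names = list(dm.ids)
    data = dm.data
    best = None
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = tuple(sorted((names[i], names[j])))
            cand = (-data[i, j], pair)
            if best is None or cand < best:
                best = cand
    dmax = -best[0]
    if dmax <= 0.0:
        raise ValueError("all branch lengths are zero; midpoint undefined")
    a_name, b_name = best[1]
    tip_by_name = {t.name: t for t in work.tips()}
    a, b = tip_by_name[a_name], tip_by_name[b_name]
    lca = work.lowest_common_ancestor([a, b])
    path_a = _path_up(a, lca)
    path_b = _path_up(b, lca)
    # walk from a toward b; nodes on the path in order, with edge lengths
    path_nodes = path_a + [lca] + list(reversed(path_b))
    half = dmax / 2.0
    walked = 0.0
    for k in range(len(path_nodes) - 1):
        u, v = path_nodes[k], path_nodes[k + 1]
        child = u if u.parent is v else v  # the lower node owns the edge length
        edge = child.length or 0.0
        if walked + edge >= half - 1e-12:
            offset = half - walked  # distance from u along the edge
            return _root_on_edge(work, u, v, child, offset)
        walked += edge
    raise RuntimeError("midpoint walk exceeded path length")  # pragma: no cover


def _path_up(node: TreeNode, ancestor: TreeNode) -> list[TreeNode]:
    path = []
    cur = node
    while cur is not ancestor:
        path.append(cur)
        cur = cur.parent
    return path


def _root_on_edge(tree: TreeNode, u: TreeNode, v: TreeNode, child: TreeNode,
                  offset: float) -> TreeNode:
    """Split edge (u, v) at ``offset`` from u and root the tree there."""
    parent = v if child is u else u
    edge = child.length or 0.0
    from_child = offset if child is u else edge - offset
    from_child = min(max(from_child, 0.0), edge)
    if from_child <= 1e-12 and not child.is_tip():
        rooted = child.root_at(reset=True)
    else:
        mid = TreeNode(name="_midpoint", length=edge - from_child)
        parent.remove(child)
        child.length = from_child
        mid.append(child)
        parent.append(mid)
        rooted = mid.root_at(reset=True)
        rooted.name = None
    for node in rooted.traverse(include_self=True):
        if not hasattr(node, "support"):
            node.support = None
    rooted.length = 0.0
    return rooted
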