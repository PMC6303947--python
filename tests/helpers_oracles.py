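"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's data structures and
algorithmic shortcuts: alignment scores come from a plain recursive
state DP over (i, j, gap-state) with run-length gap costing; contacts
from an all-pairs distance scan; NJ topologies from exhaustive
least-squares fits over enumerated topologies.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


def global_oracle(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score; gap of length k costs open + (k-1)*ext."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, score_fn(a[i], b[j]) + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, rec(i + 1, j, 1) - cost)
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, rec(i, j + 1, 2) - cost)
        return best

    return rec(0, 0, 0)


def local_oracle(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score (floor at 0)."""

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int, state: int) -> float:
        # best score of an alignment ending exactly at (i, j) in `state`
        # (0: last column is a match; 1: gap consuming a; 2: gap consuming b)
        if state == 0:
            if i == 0 or j == 0:
                return -math.inf
            prev = max(0.0, end_at(i - 1, j - 1, 0), end_at(i - 1, j - 1, 1),
                       end_at(i - 1, j - 1, 2))
            return score_fn(a[i - 1], b[j - 1]) + prev
        if state == 1:
            if i == 0:
                return -math.inf
            return max(end_at(i - 1, j, 0) - gap_open,
                       end_at(i - 1, j, 1) - gap_extend,
                       end_at(i - 1, j, 2) - gap_open)
        if j == 0:
            return -math.inf
        return max(end_at(i, j - 1, 0) - gap_open,
                   end_at(i, j - 1, 2) - gap_extend,
                   end_at(i, j - 1, 1) - gap_open)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, end_at(i, j, 0))
    return best


def contact_oracle(model, ligand, radius: float) -> set:
    """All-pairs heavy-atom scan for residues within radius of the ligand."""
    lig = [(a.x, a.y, a.z) for a in ligand.atoms if not a.is_hydrogen]
    found = set()
    for res in model.residues:
        if res.het or res.is_water:
            continue
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            for (x, y, z) in lig:
                d = math.sqrt((atom.x - x) ** 2 + (atom.y - y) ** 2 + (atom.z - z) ** 2)
                if d <= radius:
                    found.add(res.key)
    return found


# ---------------------------------------------------------------------------
# trees


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree topology with positive branch lengths.

    Returns (labels, leaf-to-leaf path distance matrix, edge list) built
    by sequential taxon insertion; distances are computed by summing the
    generating branch lengths, independently of any NJ code.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # graph as adjacency: node -> {neighbor: length}
    adj: dict[object, dict] = {labels[0]: {}, labels[1]: {}, labels[2]: {}, "i0": {}}
    for leaf in labels[:3]:
        w = float(rng.uniform(0.1, 1.0))
        adj["i0"][leaf] = w
        adj[leaf] = {"i0": w}
    next_internal = 1
    for k in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        split = float(rng.uniform(0.2, 0.8)) * w
        new = f"i{next_internal}"
        next_internal += 1
        del adj[u][v]
        del adj[v][u]
        adj[new] = {u: split, v: w - split}
        adj[u][new] = split
        adj[v][new] = w - split
        leaf_w = float(rng.uniform(0.1, 1.0))
        adj[new][labels[k]] = leaf_w
        adj[labels[k]] = {new: leaf_w}
    # all-pairs distances via BFS accumulation
    dist = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur].items():
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        dist[src] = seen
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = dist[a][b]
    d = (d + d.T) / 2.0  # exact symmetry despite float summation order
    splits = tree_splits(adj, labels)
    return labels, d, splits


def tree_splits(adj, labels) -> set:
    """Non-trivial bipartitions of an adjacency-map tree (canonical sides)."""
    anchor = sorted(labels)[0]
    full = frozenset(labels)
    out = set()
    for u in adj:
        for v in adj[u]:
            if str(u) < str(v):
                side = _leaves_beyond(adj, u, v, set(labels))
                if anchor in side:
                    side = full - side
                if 2 <= len(side) <= len(labels) - 2:
                    out.add(frozenset(side))
    return out


def _leaves_beyond(adj, u, v, labels) -> frozenset:
    # leaves reachable from v without passing through u
    seen = {v}
    stack = [v]
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if nxt != u and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(x for x in seen if x in labels)


def quartet_ls_topology(labels, d) -> frozenset:
    """Least-squares best topology for 4 taxa, enumerated exhaustively.

    Returns the canonical split of the winning quartet topology, fitted
    by ordinary least squares over the 5 branch lengths.
    """
    assert len(labels) == 4
    best = None
    for pair in itertools.combinations(range(4), 2):
        if 0 in pair:
            a, b = pair
            c, e = [x for x in range(4) if x not in pair]
            # design matrix rows: d(ab), d(ac), d(ae), d(bc), d(be), d(ce)
            # unknowns: la, lb, lc, le, lm (internal)
            rows = [
                (a, b, [0, 0]), (a, c, [1, 0]), (a, e, [1, 0]),
                (b, c, [1, 0]), (b, e, [1, 0]), (c, e, [0, 1]),
            ]
            X, y = [], []
            idx = {a: 0, b: 1, c: 2, e: 3}
            for (p, q, mid) in rows:
                row = [0.0] * 5
                row[idx[p]] = 1.0
                row[idx[q]] = 1.0
                row[4] = float(mid[0])
                X.append(row)
                y.append(d[p, q])
            X, y = np.array(X), np.array(y)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((X @ coef - y) ** 2).sum())
            split = frozenset({labels[c], labels[e]})
            if best is None or rss < best[0] - 1e-12:
                best = (rss, split)
    return best[1]
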