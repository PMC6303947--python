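import math

import numpy as np
import pytest
from helpers_oracles import quartet_ls_topology, random_additive_tree

from subfamkit.io import parse_newick
from subfamkit.phylo import (
    DistanceMatrix,
    SaturatedPairError,
    bipartitions,
    bootstrap_supports,
    distance_matrix,
    midpoint_root,
    nj_tree,
)

from conftest import make_alignment


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = make_alignment({"a": "MKVL", "b": "MKVL", "c": "MKVL"})
        dm = distance_matrix(aln)
        assert np.allclose(dm.data, 0.0)

    def test_poisson_closed_form(self):
        # 10 columns, 1 mismatch between a and b -> p = 0.1
        aln = make_alignment({"a": "AAAAAAAAAA", "b": "AAAAAAAAAC", "c": "AAAAAAAAAA"})
        dm = distance_matrix(aln, model="poisson")
        assert dm[("a", "b")] == pytest.approx(-math.log(0.9))

    def test_pairwise_deletion(self):
        aln = make_alignment({"a": "MK-V", "b": "ML-V", "c": "MKAV"})
        dm = distance_matrix(aln, model="p")
        assert dm[("a", "b")] == pytest.approx(1 / 3)

    def test_poisson_dominates_p(self, small_family):
        p = distance_matrix(small_family.alignment, model="p")
        poisson = distance_matrix(small_family.alignment, model="poisson")
        assert np.all(poisson.data >= p.data - 1e-12)
        equal = np.isclose(poisson.data, p.data)
        assert np.all(p.data[equal] == 0.0)

    def test_no_shared_columns_is_error(self):
        aln = make_alignment({"a": "MK--", "b": "--VL", "c": "MKVL"})
        with pytest.raises(ValueError, match="share no"):
            distance_matrix(aln)

    def test_saturated_pair_errors_unless_clamped(self):
        rows = {"a": "A" * 30, "b": "C" * 30, "c": "A" * 30}
        with pytest.raises(SaturatedPairError):
            distance_matrix(make_alignment(rows))
        dm = distance_matrix(make_alignment(rows), clamp_saturated=True)
        assert dm[("a", "b")] == pytest.approx(5.0)


def path_distances(tree):
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b] for a in dm.ids for b in dm.ids if a < b}


class TestNJTree:
    def test_additive_quartet_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert set(bipartitions(tree)) == {frozenset({"C", "D"})}
        got = path_distances(tree)
        for i, a in enumerate(labels):
            for j in range(i + 1, 4):
                assert got[frozenset((a, labels[j]))] == pytest.approx(d[i, j], abs=1e-9)

    def test_quartet_matches_least_squares_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            labels, d, _ = random_additive_tree(4, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            (split,) = set(bipartitions(tree))
            assert split == quartet_ls_topology(labels, d)

    def test_three_leaves_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_random_additive_trees_reproduced(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            labels, d, splits = random_additive_tree(7, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            assert set(bipartitions(tree)) == splits
            got = path_distances(tree)
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    assert got[frozenset((a, labels[j]))] == pytest.approx(
                        d[i, j], abs=1e-9)

    def test_skbio_cross_check_topology(self):
        """Independent route: scikit-bio's own NJ on the same matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        labels, d, _ = random_additive_tree(6, rng)
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        def splits(t):
            leaves = sorted(x.name for x in t.tips())
            anchor, full = leaves[0], frozenset(leaves)
            out = set()
            for n in t.non_tips():
                s = frozenset(x.name for x in n.tips())
                if anchor in s:
                    s = full - s
                if 2 <= len(s) <= len(leaves) - 2:
                    out.add(s)
            return out
        assert splits(ours) == splits(theirs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


class TestBootstrapSupports:
    def test_planted_clades_fully_supported(self, small_family):
        aln = small_family.alignment
        ref = nj_tree(distance_matrix(aln))
        tree = bootstrap_supports(aln, ref, n=50, seed=3)
        truth_clades = {
            frozenset(l for l, s in small_family.truth.items() if s == sf)
            for sf in set(small_family.truth.values())
        }
        parts = bipartitions(tree)
        leaves = frozenset(small_family.truth)
        for clade in truth_clades:
            canon = clade if min(leaves) not in clade else leaves - clade
            assert canon in parts
            assert parts[canon].support == pytest.approx(1.0)

    def test_same_seed_identical_supports(self, small_family):
        aln = small_family.alignment
        ref = nj_tree(distance_matrix(aln))
        t1 = bootstrap_supports(aln, ref, n=30, seed=9)
        t2 = bootstrap_supports(aln, ref, n=30, seed=9)
        s1 = {k: v.support for k, v in bipartitions(t1).items()}
        s2 = {k: v.support for k, v in bipartitions(t2).items()}
        assert s1 == s2

    def test_supports_in_unit_interval(self, small_family):
        aln = small_family.alignment
        ref = nj_tree(distance_matrix(aln))
        tree = bootstrap_supports(aln, ref, n=20, seed=4)
        for node in bipartitions(tree).values():
            assert 0.0 <= node.support <= 1.0

    def test_identical_sequences_star_reports_no_supports(self):
        aln = make_alignment({c: "MKVL" * 5 for c in "abcd"})
        ref = nj_tree(distance_matrix(aln))
        # zero distances give a tree with no resolved internal structure or
        # arbitrary zero-length resolution; supports must never exceed those
        # of real signal and the call must not fail
        tree = bootstrap_supports(aln, ref, n=10, seed=5)
        assert tree.n_skipped_replicates == 0


class TestMidpointRoot:
    def test_root_on_longest_path(self):
        tree = parse_newick("((A:1,B:1):1,C:3);")
        rooted = midpoint_root(tree)
        dists = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert dists["C"] == pytest.approx(2.5)
        assert dists["A"] == pytest.approx(2.5)

    def test_two_leaf_symmetry(self):
        rooted = midpoint_root(parse_newick("(A:1,B:1);"))
        dists = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert dists == pytest.approx({"A": 1.0, "B": 1.0})

    def test_path_distances_preserved(self):
        rng = np.random.default_rng(13)
        labels, d, _ = random_additive_tree(6, rng)
        tree = nj_tree(DistanceMatrix(labels, d))
        before = path_distances(tree)
        after = path_distances(midpoint_root(tree))
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-9)

    def test_all_zero_lengths_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            midpoint_root(parse_newick("((A:0,B:0):0,C:0);"))
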