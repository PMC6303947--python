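import numpy as np
import pytest

from subfamkit.io import SequenceRecord
from subfamkit.msa import (
    Alignment,
    add_to_seed,
    conservation,
    logo_columns,
    reference_numbering,
    trim_columns,
)
from subfamkit.subfamilies import SubfamilyPartition

from conftest import make_alignment, random_protein


@pytest.fixture()
def seed_aln():
    return make_alignment({
        "r1": "MK-VLD",
        "r2": "MKAVLD",
        "r3": "MK-VID",
    })


class TestAddToSeed:
    def test_identical_to_seed_row_gets_same_gap_pattern(self, seed_aln, scheme):
        ext, dropped = add_to_seed(seed_aln, [SequenceRecord("n", "MKVLD")], scheme)
        assert ext.row("n").residues == "MK-VLD"
        assert dropped == {}

    def test_insertion_relative_to_seed_dropped_and_logged(self, seed_aln, scheme):
        ext, dropped = add_to_seed(seed_aln, [SequenceRecord("n", "MKAWVLD")], scheme)
        assert ext.row("n").residues == "MKAVLD"
        assert dropped == {"n": [4]}  # the inserted W, 1-based on the input

    def test_adding_nothing_returns_seed_unchanged(self, seed_aln, scheme):
        ext, _ = add_to_seed(seed_aln, [], scheme)
        assert ext.ids == seed_aln.ids
        assert [r.residues for r in ext.records] == [r.residues for r in seed_aln.records]

    def test_seed_columns_never_change(self, seed_aln, scheme):
        rng = np.random.default_rng(0)
        new = [SequenceRecord(f"n{i}", random_protein(rng, 8)) for i in range(3)]
        ext, _ = add_to_seed(seed_aln, new, scheme)
        assert ext.length == seed_aln.length
        for rid in seed_aln.ids:
            assert ext.row(rid).residues == seed_aln.row(rid).residues

    def test_id_collision_rejected(self, seed_aln, scheme):
        with pytest.raises(ValueError, match="collide"):
            add_to_seed(seed_aln, [SequenceRecord("r1", "MKVLD")], scheme)


class TestTrimColumns:
    def test_gap_fraction_at_threshold_removed(self):
        # 5 rows, column 1 has 4 gaps (0.8): removed under "at least 80%"
        aln = make_alignment({f"s{i}": row for i, row in
                              enumerate(["A-C", "A-C", "AAC", "A-C", "A-C"])})
        trimmed, removed = trim_columns(aln, 0.8)
        assert removed == [1]
        assert trimmed.length == 2

    def test_below_threshold_kept(self):
        aln = make_alignment({f"s{i}": row for i, row in
                              enumerate(["A-C", "A-C", "AAC", "AAC", "A-C"])})
        trimmed, removed = trim_columns(aln, 0.8)
        assert removed == []

    def test_idempotent_and_order_preserving(self):
        aln = make_alignment({"b": "A--C", "a": "AA-C", "c": "A--C"})
        once, removed = trim_columns(aln, 0.8)
        twice, removed2 = trim_columns(once, 0.8)
        assert removed2 == []
        assert twice.ids == ["b", "a", "c"]
        assert once.length == aln.length - len(removed)

    def test_removing_everything_is_error(self):
        aln = make_alignment({"a": "-", "b": "-", "c": "A"})
        with pytest.raises(ValueError, match="every column"):
            trim_columns(aln, 1 / 3)


class TestConservation:
    def test_invariant_column_max_information(self):
        prof = conservation(make_alignment({f"s{i}": "G" for i in range(5)}))
        assert prof.modal_frequency[0] == pytest.approx(1.0)
        assert prof.information[0] == pytest.approx(np.log2(20))

    def test_gap_counts_against_modal_frequency(self):
        rows = {f"s{i}": "D" for i in range(9)}
        rows["s9"] = "-"
        prof = conservation(make_alignment(rows))
        assert prof.modal_frequency[0] == pytest.approx(0.9)  # boundary: NOT > 0.9
        assert prof.gap_fraction[0] == pytest.approx(0.1)

    def test_uniform_column_zero_information(self):
        from subfamkit.io import AA20

        prof = conservation(make_alignment({f"s{i}": c for i, c in enumerate(AA20)}))
        assert prof.information[0] == pytest.approx(0.0, abs=1e-12)


class TestLogoColumns:
    def _partition(self):
        return SubfamilyPartition(
            subfamilies={"SF1": frozenset({"a1", "a2"}), "SF2": frozenset({"b1", "b2"})},
            unassigned=frozenset(),
        )

    def test_fully_gapped_column_excluded(self):
        aln = make_alignment({"a1": "A-", "a2": "A-", "b1": "C-", "b2": "C-"})
        included, _ = logo_columns(aln, self._partition())
        assert included == [0]

    def test_one_full_subfamily_suffices(self):
        aln = make_alignment({"a1": "AA", "a2": "AA", "b1": "C-", "b2": "C-"})
        included, mats = logo_columns(aln, self._partition())
        assert included == [0, 1]
        assert mats["SF2"].loc[1].sum() == pytest.approx(0.0)  # fully gapped there

    def test_boundary_ninety_percent_included(self):
        rows = {f"a{i}": "A" for i in range(1, 10)}
        rows["a10"] = "-"
        rows["b1"] = "-"
        part = SubfamilyPartition(
            subfamilies={"SF1": frozenset(rows) - {"b1"}, "SF2": frozenset({"b1"})},
            unassigned=frozenset(),
        )
        included, _ = logo_columns(make_alignment(rows), part)
        assert included == [0]  # 9/10 non-gap in SF1 meets the >= 0.9 rule

    def test_frequencies_sum_to_one_per_included_column(self, small_family):
        truth = small_family.truth
        part = SubfamilyPartition(
            subfamilies={
                sf: frozenset(l for l, s in truth.items() if s == sf)
                for sf in sorted(set(truth.values()))
            },
            unassigned=frozenset(),
        )
        included, mats = logo_columns(small_family.alignment, part)
        for df in mats.values():
            sums = df.sum(axis=1).to_numpy()
            assert np.allclose(sums[sums > 0], 1.0, atol=1e-12)

    def test_empty_subfamily_rejected(self):
        aln = make_alignment({"a1": "A"})
        part = SubfamilyPartition(subfamilies={"SF1": frozenset()}, unassigned=frozenset({"a1"}))
        with pytest.raises(ValueError, match="no members"):
            logo_columns(aln, part)


class TestReferenceNumbering:
    def test_gapped_reference_mapping(self):
        aln = make_alignment({"ref": "A-CD", "o": "AACD"})
        rm = reference_numbering(aln, "ref")
        assert rm.col_to_res == {0: 1, 2: 2, 3: 3}
        assert rm.column_to_residue(1) is None

    def test_gap_free_reference_identity_shift(self):
        aln = make_alignment({"ref": "ACDE"})
        rm = reference_numbering(aln, "ref")
        assert all(rm.column_to_residue(i) == i + 1 for i in range(4))

    def test_round_trip_and_count_on_random_alignments(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            residues = random_protein(rng, 30)
            gapped = "".join(
                c if rng.random() > 0.3 else "-" + c for c in residues
            )
            aln = make_alignment({"ref": gapped, "o": "A" * len(gapped)})
            rm = reference_numbering(aln, "ref")
            assert rm.n_mapped == len(gapped.replace("-", ""))
            for res in range(1, rm.n_mapped + 1):
                col = rm.residue_to_column(res)
                assert rm.column_to_residue(col) == res

    def test_absent_reference_rejected(self):
        with pytest.raises(KeyError):
            reference_numbering(make_alignment({"a": "ACD"}), "nope")
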