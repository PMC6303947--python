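import numpy as np
import pytest
from helpers_oracles import contact_oracle

from subfamkit.io import Atom, Residue, StructureModel
from subfamkit.msa import reference_numbering
from subfamkit.features import RegionDefinitions
from subfamkit.simulate import simulate_complex
from subfamkit.structure import (
    ComplexState,
    LigandClassification,
    StructureAnnotation,
    annotation_tallies,
    classify_ligands,
    complex_state,
    contacts_to_regions,
    substrate_contacts,
)

from conftest import make_alignment


def residue(name, number, xyz=(0.0, 0.0, 0.0), chain="A", het=False, element="C"):
    return Residue(
        chain=chain, number=number, icode="", name=name, het=het,
        atoms=[Atom("C1", element, 1.0, "", *xyz)],
    )


class TestClassifyLigands:
    def test_cofactor_substrate_water_split(self):
        model = StructureModel("x", [
            residue("ALA", 1),
            residue("NAD", 201, het=True),
            residue("LAC", 202, het=True),
            Residue("A", 301, "", "HOH", True, [Atom("O", "O", 1.0, "", 9, 9, 9)]),
        ])
        cls = classify_ligands(model)
        assert [r.name for r in cls.cofactors] == ["NAD"]
        assert [r.name for r in cls.substrates] == ["LAC"]
        assert [r.name for r in cls.excluded] == ["HOH"]

    def test_crystallization_additives_excluded(self):
        model = StructureModel("x", [
            residue("NAP", 201, het=True),
            residue("SO4", 202, het=True),
            residue("GOL", 203, het=True),
        ])
        cls = classify_ligands(model)
        assert cls.substrates == []
        assert [r.name for r in cls.cofactors] == ["NAP"]


class TestSubstrateContacts:
    def _model(self, positions):
        residues = [residue("LIG", 500, het=True)]
        for k, pos in enumerate(positions, start=1):
            residues.append(residue("ALA", k, xyz=pos))
        return StructureModel("toy", residues)

    def test_inside_radius_included_with_distance(self):
        model = self._model([(0, 0, 4.9)])
        cmap = substrate_contacts(model, model.het_residues()[0], 5.0)
        assert [c.min_distance for c in cmap.contacts] == [pytest.approx(4.9)]

    def test_outside_radius_excluded(self):
        model = self._model([(0, 0, 5.1)])
        cmap = substrate_contacts(model, model.het_residues()[0], 5.0)
        assert cmap.contacts == []

    def test_exactly_at_radius_included(self):
        model = self._model([(0, 0, 5.0)])
        cmap = substrate_contacts(model, model.het_residues()[0], 5.0)
        assert len(cmap.contacts) == 1

    def test_hydrogens_ignored_both_sides(self):
        lig = Residue("A", 500, "", "LIG", True, [
            Atom("C1", "C", 1.0, "", 0, 0, 0),
            Atom("H1", "H", 1.0, "", 0, 0, 6.0),
        ])
        res = Residue("A", 1, "", "ALA", False, [
            Atom("CA", "C", 1.0, "", 0, 0, 7.0),
            Atom("HA", "H", 1.0, "", 0, 0, 1.0),
        ])
        cmap = substrate_contacts(StructureModel("x", [lig, res]), lig, 5.0)
        assert cmap.contacts == []

    def test_other_subunit_flagged(self):
        model = StructureModel("x", [
            residue("LIG", 500, het=True),
            residue("TYR", 1, xyz=(0, 0, 3.0), chain="B"),
        ])
        cmap = substrate_contacts(model, model.het_residues()[0], 5.0)
        assert cmap.contacts[0].other_subunit

    def test_ligand_without_heavy_atoms_is_error(self):
        lig = Residue("A", 500, "", "LIG", True, [Atom("H1", "H", 1.0, "", 0, 0, 0)])
        with pytest.raises(ValueError, match="heavy"):
            substrate_contacts(StructureModel("x", [lig, residue("ALA", 1)]), lig, 5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_complexes_match_brute_force(self, seed):
        model, expected = simulate_complex(n_contacts=6, radius=5.0, seed=seed)
        ligand = model.het_residues()[0]
        cmap = substrate_contacts(model, ligand, 5.0)
        assert cmap.residue_keys() == contact_oracle(model, ligand, 5.0)
        assert cmap.residue_keys() == expected.residue_keys()

    def test_rigid_motion_invariance(self):
        model, _ = simulate_complex(n_contacts=5, radius=5.0, seed=3)
        ligand = model.het_residues()[0]
        before = substrate_contacts(model, ligand, 5.0).residue_keys()
        # rotate by a random rotation and translate
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = np.array([10.0, -5.0, 2.5])
        moved = []
        for res in model.residues:
            atoms = []
            for a in res.atoms:
                x, y, z = q @ np.array([a.x, a.y, a.z]) + shift
                atoms.append(Atom(a.name, a.element, a.occupancy, a.altloc, x, y, z))
            moved.append(Residue(res.chain, res.number, res.icode, res.name, res.het, atoms))
        moved_model = StructureModel("moved", moved)
        after = substrate_contacts(moved_model, moved_model.het_residues()[0], 5.0).residue_keys()
        assert before == after

    def test_radius_monotonicity(self):
        model, _ = simulate_complex(n_contacts=8, radius=5.0, seed=6)
        ligand = model.het_residues()[0]
        sets = [
            substrate_contacts(model, ligand, r).residue_keys()
            for r in (2.0, 3.5, 5.0, 8.0)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestComplexState:
    def _cls(self, cof=None, sub=None):
        c = LigandClassification()
        if cof:
            c.cofactors.append(residue(cof, 201, het=True))
        if sub:
            c.substrates.append(residue(sub, 202, het=True))
        return c

    def test_reduced_reduced_is_true_ternary(self):
        state = complex_state(self._cls("NAI", "LAC"))  # NADH + lactate
        assert state.state == "true_ternary"

    def test_mixed_redox_is_plain_ternary(self):
        state = complex_state(self._cls("NAD", "LAC"))
        assert state.state == "ternary"

    def test_cofactor_only_is_binary(self):
        assert complex_state(self._cls("NAP")).state == "binary"

    def test_nothing_bound_is_apo(self):
        assert complex_state(self._cls()).state == "apo"

    def test_unknown_redox_never_true_ternary(self):
        state = complex_state(self._cls("NAD", "ZZZ"))
        assert state.state == "ternary"
        assert "unknown" in state.note


class TestAnnotationTallies:
    def test_binary_ternary_true_ternary_counts(self):
        rows = [
            StructureAnnotation("1aaa", "P1", (), "NAD", "oxidized", None),      # binary
            StructureAnnotation("1bbb", "P2", ("LAC",), "NAI", "reduced", "reduced"),   # true
            StructureAnnotation("1ccc", "P3", ("LAC",), "NAD", "oxidized", "reduced"),  # ternary
            StructureAnnotation("1ddd", "P4", ("SO4",), "NAD", "oxidized", None),  # binary (SO4 excluded)
            StructureAnnotation("1eee", "P5", (), None, None, None),             # apo
            StructureAnnotation("1fff", "P6", ("PYR",), "NAD", "oxidized", "oxidized"),  # true
        ]
        tallies = annotation_tallies(rows)
        assert tallies == {
            "n_structures": 6,
            "n_apo": 1,
            "n_binary": 2,
            "n_ternary": 3,
            "n_true_ternary": 2,
        }


class TestContactsToRegions:
    def test_contacts_projected_and_other_subunit_primed(self):
        # reference gap-free, so structure numbering == reference numbering
        L = 120
        aln = make_alignment({"REF": "A" * L, "rowA": "A" * L, "rowB": "A" * L})
        refmap = reference_numbering(aln, "REF")
        regions = RegionDefinitions(regions={"b4-a4": (70, 78)})
        from subfamkit.structure import Contact, ContactMap

        cmap = ContactMap("x", ("A", "LIG", 500), [
            Contact("A", 73, "", "VAL", 3.2, False),
            Contact("B", 74, "", "TYR", 4.0, True),
            Contact("A", 10, "", "GLY", 4.5, False),
            Contact("A", 999, "", "ALA", 4.5, False),
        ], 5.0)
        out = contacts_to_regions(cmap, aln, refmap, regions,
                                  {"A": "rowA", "B": "rowB"})
        assert out["per_region"] == {
            "b4-a4": 1,
            "b4-a4'": 1,
            "outside named regions": 1,
        }
        assert [c.number for c in out["unmapped"]] == [999]
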