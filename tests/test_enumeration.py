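"""R-group tables, enumeration, stereo-preserving assembly, verification."""

from types import SimpleNamespace

import pytest
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler

from alchemid import (
    FixtureSpec,
    UnsupportedBond,
    assemble,
    build_rgroup_table,
    enumerate_assignments,
    find_core,
    generate_intermediates,
    make_pair,
    site_partition,
    verify_parent_reconstruction,
)

from conftest import rec
from oracles import molzip_recombinations


def cip_codes(mol):
    mol = Chem.Mol(mol)
    rdCIPLabeler.AssignCIPLabels(mol)
    return {
        a.GetIdx(): a.GetPropsAsDict().get("_CIPCode")
        for a in mol.GetAtoms()
        if a.HasProp("_CIPCode")
    }


class TestRGroupTable:
    def test_identical_parents_nothing_differs(self):
        a, b = rec("Cc1ccc(F)cc1", "a"), rec("Cc1ccc(F)cc1", "b")
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        assert not any(table.differing)

    def test_three_differing_site_groups(self, three_site_pair):
        a, b = three_site_pair
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        assert table.n_differing == 3

    def test_stereo_record_captured_at_chiral_cut(self):
        a = rec("c1cc(F)cc(c1)N", "a")
        b = rec("c1cc(Cl)cc(c1)[C@](C)(F)CO", "b")
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        chiral_groups = [
            rg_b for _rg_a, rg_b in table.entries if rg_b.stereo_record
        ]
        assert chiral_groups, "expected a stereo record for the chiral fragment"

    def test_double_bond_crossing_is_rejected(self):
        # the MCS extends to the carbonyl carbon, so the cut would fall on C=O
        a = rec("O[C@@H](CC(N)=O)c1ccc(F)cc1", "a")
        b = rec("O[C@@H](CCO)c1ccc(Cl)cc1", "b")
        core = find_core(a, b)
        with pytest.raises(UnsupportedBond):
            build_rgroup_table(a, b, core)

    def test_implicit_h_group_has_zero_heavy_atoms(self, three_site_pair):
        a, b = three_site_pair
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        h_groups = [rg_b for _a, rg_b in table.entries if rg_b.is_implicit_h]
        assert len(h_groups) == 1
        assert h_groups[0].heavy_atom_count == 0


class TestEnumerateAssignments:
    @pytest.mark.parametrize("k,expected", [(0, 0), (1, 0), (2, 2), (3, 6), (5, 30)])
    def test_count_law(self, k, expected):
        table = SimpleNamespace(n_differing=k)
        vecs = enumerate_assignments(table)
        assert len(vecs) == expected
        assert len(set(vecs)) == len(vecs)
        assert ("A",) * k not in vecs and ("B",) * k not in vecs

    def test_deterministic_binary_order(self):
        table = SimpleNamespace(n_differing=2)
        assert enumerate_assignments(table) == [("A", "B"), ("B", "A")]


class TestAssembly:
    def test_all_a_assignment_reconstructs_parent(self, three_site_pair):
        a, b = three_site_pair
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        rebuilt = assemble(core, ("A",) * 3, table)
        assert rebuilt.canonical_form == a.canonical_form

    def test_junction_stereocenter_keeps_orientation(self, stereo_junction_pair):
        a, b = stereo_junction_pair
        iset = generate_intermediates(a, b)
        assert iset.parents_reconstructed
        # every candidate keeps an R center (as both parents have)
        parent_cips = set(cip_codes(a.mol).values())
        for cand in iset.candidates:
            codes = set(cip_codes(cand.mol).values())
            assert codes == parent_cips

    def test_fused_group_transfers_ring_intact(self, fused_pair):
        a, b = fused_pair
        iset = generate_intermediates(a, b)
        n_rings_b = b.mol.GetRingInfo().NumRings()
        fused_gi = next(
            gi for gi, g in enumerate(iset.table.site_groups) if len(g) > 1
        )
        took_fused = [
            c
            for c in iset.candidates
            if any(
                at.HasProp("ai_group")
                and at.GetIntProp("ai_group") == fused_gi
                and at.GetProp("ai_origin") == "B"
                for at in c.mol.GetAtoms()
            )
        ]
        assert took_fused
        for cand in took_fused:
            assert cand.mol.GetRingInfo().NumRings() >= n_rings_b

    def test_ez_double_bond_preserved_through_reassembly(self):
        for marker in ("/C=C/", "/C=C\\"):
            a = rec(f"c1cc(F)cc(c1){marker}C", "a")
            b = rec("c1cc(Cl)cc(c1)N", "b")
            iset = generate_intermediates(a, b)
            assert iset.parents_reconstructed
            with_ene = [
                c for c in iset.candidates if "C=C" in c.canonical_form
            ]
            assert with_ene
            for cand in with_ene:
                assert "/" in cand.canonical_form or "\\" in cand.canonical_form

    def test_provenance_partition(self, three_site_pair):
        a, b = three_site_pair
        iset = generate_intermediates(a, b)
        core_size = iset.core.num_atoms
        for cand in iset.candidates:
            for atom in cand.mol.GetAtoms():
                role = atom.GetProp("ai_role")
                origin = atom.GetProp("ai_origin")
                assert role in ("core", "shared", "rgroup")
                assert origin in ("A", "B")
            n_core = sum(
                1 for at in cand.mol.GetAtoms() if at.GetProp("ai_role") == "core"
            )
            assert n_core == core_size

    def test_core_conserved_in_every_candidate(self, three_site_pair):
        a, b = three_site_pair
        iset = generate_intermediates(a, b)
        query = Chem.MolFromSmarts(iset.core.smarts)
        for cand in iset.candidates:
            assert cand.mol.HasSubstructMatch(query)


class TestVerifyParentReconstruction:
    def test_achiral_single_site_pair_verifies(self):
        a, b = rec("Cc1ccc(F)cc1", "a"), rec("Cc1ccc(Cl)cc1", "b")
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        assert verify_parent_reconstruction(a, b, core, table)

    def test_dropping_stereo_records_breaks_reconstruction(self):
        # quaternary stereocenter at the junction: reattachment appends the
        # junction bond last, an odd permutation of the recorded order, so
        # skipping parity restoration must flip the center and be caught
        a = rec("c1cc(F)cc(c1)N", "a")
        b = rec("c1cc(Cl)cc(c1)[C@](C)(F)CO", "b")
        core = find_core(a, b)
        table = build_rgroup_table(a, b, core)
        assert verify_parent_reconstruction(a, b, core, table, stereo_records=True)
        assert not verify_parent_reconstruction(
            a, b, core, table, stereo_records=False
        )

    def test_core_stereo_mismatch_is_flagged(self):
        # parents whose shared-core stereocenter has opposite parity cannot
        # both be rebuilt from one skeleton: the pair must be flagged
        a = rec("C[C@@H](N)Cc1cccc(F)c1", "a")
        b = rec("C[C@H](N)Cc1cccc(Cl)c1", "b")
        iset = generate_intermediates(a, b)
        assert not iset.parents_reconstructed


class TestGenerateIntermediates:
    def test_identity_pair_yields_nothing(self):
        a, b = rec("Cc1ccc(F)cc1", "a"), rec("Cc1ccc(F)cc1", "b")
        iset = generate_intermediates(a, b)
        assert iset.candidates == []
        assert iset.parents_reconstructed

    def test_three_site_pair_yields_six(self, three_site_pair):
        iset = generate_intermediates(*three_site_pair)
        assert len(iset.candidates) == 6

    def test_candidates_distinct_and_not_parents(self, three_site_pair):
        a, b = three_site_pair
        iset = generate_intermediates(a, b)
        forms = [c.canonical_form for c in iset.candidates]
        assert len(set(forms)) == len(forms)
        assert a.canonical_form not in forms and b.canonical_form not in forms

    def test_argument_order_does_not_change_candidate_set(self, three_site_pair):
        a, b = three_site_pair
        fwd = generate_intermediates(a, b)
        back = generate_intermediates(b, a)
        assert {c.canonical_form for c in fwd.candidates} == {
            c.canonical_form for c in back.candidates
        }

    def test_matches_independent_molzip_route(self, three_site_pair):
        a, b = three_site_pair
        iset = generate_intermediates(a, b)
        oracle = molzip_recombinations(
            a.canonical_form, b.canonical_form, "c1ccccc1"
        )
        assert {c.canonical_form for c in iset.candidates} == oracle

    def test_names_follow_numbering_convention(self, three_site_pair):
        iset = generate_intermediates(*three_site_pair, pair_id="set1")
        assert [c.name for c in iset.candidates] == [f"set1I{i}" for i in range(6)]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_count_law_on_planted_fixtures(self, k):
        a, b, expected_k = make_pair(FixtureSpec(differing_sites=k, seed=11))
        iset = generate_intermediates(a, b)
        assert iset.table.n_differing == expected_k == k
        assert len(iset.candidates) == 2**k - 2
        assert not iset.failures
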