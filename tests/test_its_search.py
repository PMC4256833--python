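"""CSP cycle search: solver vs oracle, symmetry, extended-model pruning."""

import pytest

from itsmap.chem_graph import parse_reaction
from itsmap.fixtures import plant_random_reaction
from itsmap.its_layouts import default_catalog, homovalent_cycle
from itsmap.its_search import (
    ModelError,
    brute_force_candidates,
    build_model,
    check_candidate,
    enumerate_candidates,
    first_candidate,
)
from itsmap.neighborhoods import sibling_hydrogen_removal


def _keys(cands):
    return {(c.educt_cycle, c.product_cycle) for c in cands}


@pytest.fixture(scope="module")
def h2_ethene():
    return parse_reaction("[H][H].C=C>>CC")


class TestModelConstruction:
    def test_basic_domains_cover_all_atoms(self, kegg):
        m = build_model(kegg["R00013"], homovalent_cycle(6))
        for dom in m.domains_i + m.domains_o:
            assert len(dom) == 14

    def test_extended_domains_exclude_sibling_hydrogens(self, kegg):
        r = kegg["R00013"]
        m = build_model(r, homovalent_cycle(6), mode="extended")
        h_rem = sibling_hydrogen_removal(r.educts)
        assert h_rem == m.h_rem_i
        for dom in m.domains_i:
            assert not dom & h_rem

    def test_identity_reaction_builds_without_requirements(self):
        r = parse_reaction("O>>O")
        m = build_model(r, homovalent_cycle(4), mode="extended")
        assert not m.label_requirements

    def test_unbalanced_reaction_rejected(self):
        r = parse_reaction("C>>N", check_balance=False)
        with pytest.raises(ModelError):
            build_model(r, homovalent_cycle(4))


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [4, 6])
    def test_benchmark_reaction(self, kegg, k):
        r = kegg["R00013"]
        lay = homovalent_cycle(k)
        assert _keys(enumerate_candidates(build_model(r, lay))) == _keys(
            brute_force_candidates(r, lay)
        )

    @pytest.mark.parametrize("k", [4, 6, 8])
    def test_diels_alder(self, diels_alder, k):
        lay = homovalent_cycle(k)
        assert _keys(enumerate_candidates(build_model(diels_alder, lay))) == _keys(
            brute_force_candidates(diels_alder, lay)
        )

    def test_small_explicit_hydrogen_reaction(self, h2_ethene):
        lay = homovalent_cycle(4)
        csp = _keys(enumerate_candidates(build_model(h2_ethene, lay)))
        bf = _keys(brute_force_candidates(h2_ethene, lay))
        assert csp == bf
        assert csp  # hydrogenation admits 4-cycles

    def test_all_catalog_layouts_on_ambivalent_fixture(self, meisenheimer):
        for lay in default_catalog():
            csp = _keys(enumerate_candidates(build_model(meisenheimer, lay)))
            bf = _keys(brute_force_candidates(meisenheimer, lay))
            assert csp == bf, lay.name

    def test_size_guard(self, kegg):
        with pytest.raises(ModelError):
            brute_force_candidates(kegg["R00018"], homovalent_cycle(4))


class TestSolutions:
    def test_diels_alder_4_cycles_never_extend_but_a_6_cycle_does(self, diels_alder):
        from itsmap.map_extension import enumerate_atom_maps

        # 4-cycles exist as candidates (double bonds can lose one order) but
        # none extends to a complete atom map
        four = enumerate_candidates(build_model(diels_alder, homovalent_cycle(4)))
        assert four
        assert all(not enumerate_atom_maps(diels_alder, c) for c in four)
        sols = enumerate_candidates(build_model(diels_alder, homovalent_cycle(6)))
        assert sols
        # some candidate uses exactly the six reacting carbons
        n = next(a.index for a in diels_alder.educts.atoms if a.element == "N")
        methyl = 2
        assert any(
            n not in c.educt_cycle and methyl not in c.educt_cycle for c in sols
        )

    def test_first_candidate_is_first_of_enumeration(self, diels_alder):
        m = build_model(diels_alder, homovalent_cycle(6))
        sols = enumerate_candidates(m)
        first = first_candidate(build_model(diels_alder, homovalent_cycle(6)))
        assert (first.educt_cycle, first.product_cycle) == (
            sols[0].educt_cycle,
            sols[0].product_cycle,
        )

    def test_infeasible_returns_none(self, diels_alder):
        assert first_candidate(build_model(diels_alder, homovalent_cycle(8))) is None

    def test_identity_reaction_has_no_candidates(self):
        r = parse_reaction("O>>O")
        for lay in default_catalog():
            assert enumerate_candidates(build_model(r, lay)) == []

    def test_candidates_satisfy_their_invariants(self, kegg):
        r = kegg["R00013"]
        for c in enumerate_candidates(build_model(r, homovalent_cycle(6))):
            ok, errs = check_candidate(r, c)
            assert ok, errs

    def test_deterministic_order(self, diels_alder):
        a = enumerate_candidates(build_model(diels_alder, homovalent_cycle(6)))
        b = enumerate_candidates(build_model(diels_alder, homovalent_cycle(6)))
        assert [(c.educt_cycle, c.product_cycle) for c in a] == [
            (c.educt_cycle, c.product_cycle) for c in b
        ]


class TestSymmetryBreaking:
    @pytest.mark.parametrize("k", [4, 6])
    def test_order_constraint_keeps_one_of_k_equivalent_assignments(self, kegg, k):
        """Each geometric cycle admits k assignments: k/2 phase-preserving
        rotations times two traversal directions (a reversed traversal also
        begins with a breaking edge).  The order constraint keeps exactly one,
        so disabling it multiplies the count by k."""
        r = kegg["R00013"]
        on = enumerate_candidates(build_model(r, homovalent_cycle(k)))
        off = enumerate_candidates(
            build_model(r, homovalent_cycle(k), symmetry_breaking=False)
        )
        assert len(off) == k * len(on)

    def test_unbroken_set_closed_under_rotation_by_two(self, h2_ethene):
        lay = homovalent_cycle(4)
        off = _keys(
            enumerate_candidates(build_model(h2_ethene, lay, symmetry_breaking=False))
        )
        rotated = {
            (ec[2:] + ec[:2], pc[2:] + pc[:2]) for ec, pc in off
        }
        assert rotated == off


class TestExtendedModel:
    @pytest.mark.parametrize("rid, k", [("R00013", 6), ("R00048", 4)])
    def test_extended_candidates_subset_of_basic(self, kegg, rid, k):
        r = kegg[rid]
        basic = _keys(enumerate_candidates(build_model(r, homovalent_cycle(k))))
        ext = _keys(
            enumerate_candidates(build_model(r, homovalent_cycle(k), mode="extended"))
        )
        assert ext <= basic
        assert len(ext) < len(basic)

    def test_degree_semantics_switch(self, kegg):
        # both semantics are available and each agrees with the oracle run
        # under the same semantics
        r = kegg["R00013"]
        for mode in ("edges", "bond_order_sum"):
            sols = _keys(
                enumerate_candidates(
                    build_model(r, homovalent_cycle(4), degree_mode=mode)
                )
            )
            oracle = _keys(
                brute_force_candidates(r, homovalent_cycle(4), degree_mode=mode)
            )
            assert sols == oracle

    def test_planted_candidate_survives_extended_pruning(self):
        pr = plant_random_reaction(8, 6, homovalent_cycle(6), seed=11)
        ext = _keys(
            enumerate_candidates(
                build_model(pr.reaction, homovalent_cycle(6), mode="extended")
            )
        )
        key = (pr.planted_candidate.educt_cycle, pr.planted_candidate.product_cycle)
        assert key in ext
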