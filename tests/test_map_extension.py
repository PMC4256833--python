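"""Relabeling, hydrogen collapsing and isomorphism-based map extension."""

from itertools import permutations

import pytest

from itsmap.chem_graph import AtomMap, parse_reaction
from itsmap.fixtures import plant_random_reaction
from itsmap.its_layouts import homovalent_cycle
from itsmap.its_search import build_model, enumerate_candidates
from itsmap.map_extension import (
    MapExtensionError,
    collapse_nonits_hydrogens,
    enumerate_atom_maps,
    relabel_its_edges,
    verify_atom_map,
)


def _da_candidates(diels_alder, k=6):
    return enumerate_candidates(build_model(diels_alder, homovalent_cycle(k)))


class TestRelabeling:
    def test_marker_counts_on_the_diels_alder_cycle(self, diels_alder):
        cand = _da_candidates(diels_alder)[0]
        pair = relabel_its_edges(diels_alder, cand)
        for mat in (pair.educt_matrix, pair.product_matrix):
            entries = [e for nbrs in mat.values() for e in nbrs.values()]
            assert entries.count("b") == 6  # 3 broken bonds, stored twice
            assert entries.count("f") == 6

    def test_non_cycle_entries_untouched(self, diels_alder):
        cand = _da_candidates(diels_alder)[0]
        pair = relabel_its_edges(diels_alder, cand)
        cycle_pairs = {
            frozenset((cand.educt_cycle[i], cand.educt_cycle[(i + 1) % cand.k]))
            for i in range(cand.k)
        }
        for u, nbrs in diels_alder.educts.adj.items():
            for v, order in nbrs.items():
                if frozenset((u, v)) not in cycle_pairs:
                    assert pair.educt_matrix[u][v] == order

    def test_broken_edges_had_educt_bonds(self, diels_alder):
        for cand in _da_candidates(diels_alder):
            for i in range(cand.k):
                j = (i + 1) % cand.k
                c = cand.layout.edge_changes[i]
                if c < 0:
                    assert (
                        diels_alder.educts.order(
                            cand.educt_cycle[i], cand.educt_cycle[j]
                        )
                        >= 1
                    )
                if c > 0:
                    assert (
                        diels_alder.products.order(
                            cand.product_cycle[i], cand.product_cycle[j]
                        )
                        >= 1
                    )

    def test_mismatched_candidate_rejected(self, diels_alder, kegg):
        cand = _da_candidates(diels_alder)[0]
        with pytest.raises(MapExtensionError):
            relabel_its_edges(kegg["R00013"], cand)


class TestCollapsing:
    def test_hydrogenation_collapse_bookkeeping(self):
        rxn = parse_reaction("[H][H].C=C>>CC")
        for cand in enumerate_candidates(build_model(rxn, homovalent_cycle(4))):
            pair = relabel_its_edges(rxn, cand)
            g_e, abs_e, g_p, abs_p = collapse_nonits_hydrogens(rxn, pair)
            # collapsed vertices + absorbed hydrogens account for every atom
            assert g_e.number_of_nodes() + sum(map(len, abs_e.values())) == len(
                rxn.educts
            )
            assert g_p.number_of_nodes() + sum(map(len, abs_p.values())) == len(
                rxn.products
            )
            assert g_e.number_of_nodes() < len(rxn.educts)
            # cycle atoms are never absorbed
            assert set(cand.educt_cycle) <= set(g_e.nodes)
            assert set(cand.product_cycle) <= set(g_p.nodes)

    def test_spectator_water_collapses_to_one_node(self):
        # water never touches the cycle, so it becomes a single O node
        # labelled with two absorbed hydrogens
        rxn = parse_reaction("O.[H][H].C=C>>O.CC")
        cands = enumerate_candidates(build_model(rxn, homovalent_cycle(4)))
        o_idx = next(a.index for a in rxn.educts.atoms if a.element == "O")
        water = {o_idx} | set(rxn.educts.adj[o_idx])
        cand = next(c for c in cands if not water & set(c.educt_cycle))
        pair = relabel_its_edges(rxn, cand)
        g_e, abs_e, _, _ = collapse_nonits_hydrogens(rxn, pair)
        assert o_idx in g_e
        assert len(abs_e[o_idx]) == 2
        assert g_e.nodes[o_idx]["lbl"][3] == 2  # absorbed-hydrogen count


class TestEnumeration:
    def test_diels_alder_yields_exactly_one_map(self, diels_alder):
        maps = []
        for cand in _da_candidates(diels_alder):
            maps.extend(enumerate_atom_maps(diels_alder, cand))
        unique = {m.as_pairs() for m in maps}
        assert len(unique) == 1
        amap = maps[0]
        ok, _ = verify_atom_map(diels_alder, amap)
        assert ok
        from itsmap.chem_graph import reaction_matrix_rows

        rows = reaction_matrix_rows(diels_alder, amap.mapping)
        changed = [x for x, row in rows.items() if row["bond_changes"]]
        assert len(changed) == 6  # the cycle covers six atoms, the rest is static

    def test_planted_map_recovered(self):
        pr = plant_random_reaction(7, 4, homovalent_cycle(4), seed=3)
        maps = enumerate_atom_maps(pr.reaction, pr.planted_candidate)
        assert pr.planted_map.as_pairs() in {m.as_pairs() for m in maps}

    def test_completeness_against_exhaustive_bijections(self):
        """On a tiny instance, collapse + isomorphism finds exactly the maps an
        exhaustive bijection search over the relabeled graphs finds."""
        rxn = parse_reaction("[H][H].C=C>>CC")
        I, O = rxn.educts, rxn.products
        n = len(I)
        for cand in enumerate_candidates(build_model(rxn, homovalent_cycle(4)))[:4]:
            got = {m.as_pairs() for m in enumerate_atom_maps(rxn, cand)}
            pair = relabel_its_edges(rxn, cand)
            pinned = dict(zip(cand.educt_cycle, cand.product_cycle))
            brute = set()
            free_e = [v for v in range(n) if v not in pinned]
            free_p = [v for v in range(n) if v not in pinned.values()]
            for perm in permutations(free_p):
                m = dict(pinned)
                m.update(zip(free_e, perm))
                if any(
                    I.atoms[x].element != O.atoms[y].element for x, y in m.items()
                ):
                    continue
                ok = all(
                    pair.educt_matrix[u].get(v, 0) == pair.product_matrix[m[u]].get(m[v], 0)
                    for u in range(n)
                    for v in range(n)
                    if u != v
                ) and all(
                    I.atoms[x].lone_pairs == O.atoms[m[x]].lone_pairs
                    or x in pinned
                    for x in range(n)
                )
                if ok:
                    v_ok, _ = verify_atom_map(rxn, AtomMap(mapping=m))
                    if v_ok:
                        brute.add(tuple(sorted(m.items())))
            assert got == brute

    def test_emitted_maps_restricted_to_cycle_equal_candidate(self, diels_alder):
        for cand in _da_candidates(diels_alder):
            for m in enumerate_atom_maps(diels_alder, cand):
                for a, b in cand.pairs():
                    assert m.mapping[a] == b


class TestVerification:
    def test_element_violation_detected(self):
        r = parse_reaction("CO>>CO")
        n = len(r.educts)
        ident = {i: i for i in range(n)}
        ok, _ = verify_atom_map(r, AtomMap(mapping=ident))
        assert ok
        bad = dict(ident)
        bad[0], bad[1] = 1, 0  # C -> O
        ok, violations = verify_atom_map(r, AtomMap(mapping=bad))
        assert not ok
        assert any("element" in v for v in violations)

    def test_non_bijection_rejected(self):
        r = parse_reaction("O>>O")
        with pytest.raises(MapExtensionError):
            verify_atom_map(r, AtomMap(mapping={0: 0, 1: 0, 2: 2}))

    def test_sibling_hydrogen_transposition_stays_valid(self):
        pr = plant_random_reaction(6, 4, homovalent_cycle(4), seed=5)
        r = pr.reaction
        m = dict(pr.planted_map.mapping)
        # transpose two absorbed sibling hydrogens on some heavy atom
        for v in range(len(r.educts)):
            hs = sorted(
                w
                for w in r.educts.adj[v]
                if r.educts.atoms[w].is_hydrogen and w not in pr.planted_candidate.educt_cycle
            )
            if len(hs) >= 2:
                m[hs[0]], m[hs[1]] = m[hs[1]], m[hs[0]]
                break
        else:
            pytest.skip("no sibling hydrogens in this instance")
        ok, violations = verify_atom_map(r, AtomMap(mapping=m))
        assert ok, violations
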