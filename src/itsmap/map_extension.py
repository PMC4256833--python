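"""Extending an ITS candidate to complete atom maps.

A CSP solution only fixes the reacting cycle.  To decide whether it is a
true transition state, the remaining atoms must map onto each other with
*no further* bond changes.  Following the relabeling trick, the cycle
edges are overwritten with markers — ``f`` (formed), ``b`` (broken),
``p`` (unchanging pseudo bond) — identically on both sides, turning the
question into plain label-preserving graph isomorphism between the
marked educt and product graphs.

Hydrogen interchange symmetry would multiply isomorphisms uselessly, so
non-cycle hydrogens are first collapsed into their heavy neighbour's
label (``C·3H``); the pinned cycle correspondence is encoded as unique
positional node labels, so every isomorphism extends the candidate.
Isomorphism search uses VF2 (:class:`networkx.isomorphism.GraphMatcher`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chem_graph import AtomMap, ReactionInstance, reaction_matrix_rows
from .its_search import ITSCandidate, check_candidate

__all__ = [
    "RelabeledPair",
    "MapExtensionError",
    "relabel_its_edges",
    "collapse_nonits_hydrogens",
    "enumerate_atom_maps",
    "verify_atom_map",
]


class MapExtensionError(ValueError):
    pass


@dataclass
class RelabeledPair:
    """Educt/product adjacency with cycle edges replaced by f/b/p markers.

    Entries are bond orders (1-3) or the strings ``"f"``, ``"b"``, ``"p"``;
    all non-cycle entries equal the original matrices.
    """

    educt_matrix: dict[int, dict[int, object]]
    product_matrix: dict[int, dict[int, object]]
    candidate: ITSCandidate


def _marker(change: int) -> str:
    if change > 0:
        return "f"
    if change < 0:
        return "b"
    return "p"


def relabel_its_edges(
    reaction: ReactionInstance, candidate: ITSCandidate
) -> RelabeledPair:
    """Overwrite each cycle edge with the same marker on both sides."""
    ok, errs = check_candidate(reaction, candidate, include_degree=False)
    if not ok:
        raise MapExtensionError(f"candidate does not fit the reaction: {errs}")
    emat: dict[int, dict[int, object]] = {
        u: dict(nbrs) for u, nbrs in reaction.educts.adj.items()
    }
    pmat: dict[int, dict[int, object]] = {
        u: dict(nbrs) for u, nbrs in reaction.products.adj.items()
    }
    k = candidate.k
    ec, pc = candidate.educt_cycle, candidate.product_cycle
    for i in range(k):
        j = (i + 1) % k
        mark = _marker(candidate.layout.edge_changes[i])
        for mat, u, v in ((emat, ec[i], ec[j]), (pmat, pc[i], pc[j])):
            mat[u][v] = mark
            mat[v][u] = mark
    return RelabeledPair(educt_matrix=emat, product_matrix=pmat, candidate=candidate)


def _collapse_side(
    graph, matrix, its_vertices, its_pos
) -> tuple[nx.Graph, dict[int, list[int]]]:
    """Build the collapsed marked graph for one side.

    Returns the graph and, per kept vertex, the ascending list of absorbed
    hydrogen ids.
    """
    absorbed: dict[int, list[int]] = {}
    drop: set[int] = set()
    for a in graph.atoms:
        if not a.is_hydrogen or a.index in its_vertices:
            continue
        nbrs = list(graph.adj[a.index])
        if len(nbrs) == 1 and not graph.atoms[nbrs[0]].is_hydrogen:
            absorbed.setdefault(nbrs[0], []).append(a.index)
            drop.add(a.index)
    g = nx.Graph()
    for a in graph.atoms:
        if a.index in drop:
            continue
        h_count = a.implicit_h + len(absorbed.get(a.index, []))
        if a.index in its_vertices:
            # charge/lone pairs may legitimately change on the cycle (the
            # candidate already validated them against the layout)
            lbl = (a.element, None, None, h_count, its_pos[a.index])
        else:
            lbl = (a.element, a.formal_charge, a.lone_pairs, h_count, -1)
        g.add_node(a.index, lbl=lbl)
    for u, nbrs in matrix.items():
        if u in drop:
            continue
        for v, entry in nbrs.items():
            if v in drop or v < u:
                continue
            g.add_edge(u, v, bond=entry)
    return g, {u: sorted(hs) for u, hs in absorbed.items()}


def collapse_nonits_hydrogens(
    reaction: ReactionInstance, pair: RelabeledPair
) -> tuple[nx.Graph, dict[int, list[int]], nx.Graph, dict[int, list[int]]]:
    """Merge non-cycle hydrogens into their heavy neighbour's node label.

    Cycle hydrogens always stay explicit; hydrogens bonded to hydrogens
    (H2) are kept as well.  Node labels carry element, charge, lone pairs,
    absorbed-hydrogen count and the pinned cycle position (-1 off-cycle).
    """
    cand = pair.candidate
    its_e = set(cand.educt_cycle)
    its_p = set(cand.product_cycle)
    pos_e = {v: i for i, v in enumerate(cand.educt_cycle)}
    pos_p = {v: i for i, v in enumerate(cand.product_cycle)}
    g_e, abs_e = _collapse_side(reaction.educts, pair.educt_matrix, its_e, pos_e)
    g_p, abs_p = _collapse_side(reaction.products, pair.product_matrix, its_p, pos_p)
    return g_e, abs_e, g_p, abs_p


def _node_match(n1, n2) -> bool:
    return n1["lbl"] == n2["lbl"]


def _edge_match(e1, e2) -> bool:
    return e1["bond"] == e2["bond"]


def enumerate_atom_maps(
    reaction: ReactionInstance, candidate: ITSCandidate
) -> list[AtomMap]:
    """All full atom maps extending the candidate's cycle correspondence.

    Every label- and marker-preserving isomorphism between the collapsed
    graphs is expanded to a full bijection, pairing absorbed hydrogens in
    ascending atom-id order; results are deduplicated as bijections and
    verified.  An empty list means the candidate is not a true transition
    state.
    """
    pair = relabel_its_edges(reaction, candidate)
    g_e, abs_e, g_p, abs_p = collapse_nonits_hydrogens(reaction, pair)
    if g_e.number_of_nodes() != g_p.number_of_nodes():
        return []
    matcher = nx.isomorphism.GraphMatcher(
        g_e, g_p, node_match=_node_match, edge_match=_edge_match
    )
    maps: list[AtomMap] = []
    seen: set[tuple] = set()
    for iso in matcher.isomorphisms_iter():
        mapping: dict[int, int] = {}
        consistent = True
        for u, v in iso.items():
            mapping[u] = v
            hs_u = abs_e.get(u, [])
            hs_v = abs_p.get(v, [])
            if len(hs_u) != len(hs_v):
                consistent = False
                break
            for hu, hv in zip(hs_u, hs_v):
                mapping[hu] = hv
        if not consistent:
            continue
        key = tuple(sorted(mapping.items()))
        if key in seen:
            continue
        seen.add(key)
        amap = AtomMap(mapping=mapping)
        ok, _ = verify_atom_map(reaction, amap)
        if ok:
            maps.append(amap)
    return maps


def verify_atom_map(
    reaction: ReactionInstance, amap: AtomMap
) -> tuple[bool, list[str]]:
    """Element preservation plus zero electron balance at every atom.

    For each educt vertex the summed bond-order changes towards its
    (mapped) neighbours plus its lone-pair change must vanish.
    """
    I, O = reaction.educts, reaction.products
    m = amap.mapping
    if sorted(m) != [a.index for a in I.atoms] or sorted(m.values()) != [
        a.index for a in O.atoms
    ]:
        raise MapExtensionError("atom map is not a bijection over all vertices")
    violations: list[str] = []
    for x, mx in m.items():
        if I.atoms[x].element != O.atoms[mx].element:
            violations.append(
                f"atom {x}: element {I.atoms[x].element} -> {O.atoms[mx].element}"
            )
    rows = reaction_matrix_rows(reaction, m)
    for x, row in rows.items():
        if row["row_sum"] != 0:
            violations.append(f"atom {x}: electron balance {row['row_sum']:+d} != 0")
    return not violations, violations
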