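"""Built-in test reactions and a planted-cycle synthetic generator.

Three kinds of inputs are provided:

* five elementary homovalent KEGG reactions (given as reaction SMILES)
  spanning cycle sizes 4-8;
* a Diels-Alder example (isoprene + vinylamine -> 1-amino-4-methyl-
  cyclohex-3-ene).  The structures are reconstructed from their published
  hydrogen-suppressed neighbourhood multisets, and that equality is
  enforced as a validation gate before the fixture is handed out;
* a [2,3]-Meisenheimer rearrangement (allyl-dimethylamine N-oxide ->
  O-allyl-N,N-dimethylhydroxylamine), an ambivalent reaction whose
  transition state is an odd cycle with an N+/O- pseudo bond;
* a seeded generator that plants a known transition-state cycle inside a
  random valence-respecting molecule and returns the ground-truth map.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .chem_graph import (
    AtomMap,
    AtomNode,
    ChemGraphError,
    MoleculeGraph,
    ReactionInstance,
    complete_hydrogens,
    parse_reaction,
)
from .its_layouts import ITSLayout
from .its_search import ITSCandidate, check_candidate
from .neighborhoods import (
    LabeledMultiset,
    NeighborhoodSignature,
    signature_multiset,
)

__all__ = [
    "PlantedReaction",
    "FixtureError",
    "kegg_reactions",
    "diels_alder_reaction",
    "meisenheimer_reaction",
    "plant_random_reaction",
    "DIELS_ALDER_SMILES",
    "KEGG_SMILES",
]


class FixtureError(ValueError):
    pass


#: elementary homovalent KEGG reactions (reaction SMILES)
KEGG_SMILES = {
    "R00013": "C(=O)=O.C(C(=O)O)(C=O)O>>C(=O)(C=O)O.C(=O)(C=O)O",
    "R00018": "N.N(CCCCN)CCCCN>>C(CCN)CN.C(CCN)CN",
    "R00048": "CC(O)CC(=O)OC(C)CC(O)=O.O>>CC(O)CC(O)=O.CC(O)CC(O)=O",
    "R00059": "N(C(=O)CCCCCN)CCCCCC(=O)O.O>>C(CC(=O)O)CCCN.C(CC(=O)O)CCCN",
    "R00207": "P(=O)(O)(O)O.O=O.CC(=O)C(=O)O>>P(=O)(OC(=O)C)(O)O.OO.C(=O)=O",
}

DIELS_ALDER_SMILES = "C=C(C)C=C.C=CN>>NC1CCC(C)=CC1"

#: reference hydrogen-suppressed neighbourhood multisets of the
#: Diels-Alder example, used to validate the reconstructed structures
_DA_REFERENCE_N_I = [
    "(C,<1C>)",
    "(C,<1C,2C>)",
    "(C,<1C,1C,2C>)",
    "(C,<1N,2C>)",
    "(C,<2C>)",
    "(C,<2C>)",
    "(C,<2C>)",
    "(N,<1C>)",
]
_DA_REFERENCE_N_O = [
    "(C,<1C>)",
    "(C,<1C,1C>)",
    "(C,<1C,1C>)",
    "(C,<1C,1C>)",
    "(C,<1C,1C,1N>)",
    "(C,<1C,1C,2C>)",
    "(C,<1C,2C>)",
    "(N,<1C>)",
]


def _parse_signature(text: str) -> NeighborhoodSignature:
    center, _, rest = text.strip("()").partition(",<")
    entries = tuple(sorted(e for e in rest.rstrip(">").split(",") if e))
    return NeighborhoodSignature(center, entries)


def reference_diels_alder_multisets() -> tuple[LabeledMultiset, LabeledMultiset]:
    n_i = LabeledMultiset(_parse_signature(s) for s in _DA_REFERENCE_N_I)
    n_o = LabeledMultiset(_parse_signature(s) for s in _DA_REFERENCE_N_O)
    return n_i, n_o


def kegg_reactions(explicit_hydrogens: bool = True) -> dict[str, ReactionInstance]:
    """The five benchmark KEGG reactions, parsed and mass-balanced."""
    return {
        rid: parse_reaction(smi, explicit_hydrogens=explicit_hydrogens, reaction_id=rid)
        for rid, smi in KEGG_SMILES.items()
    }


def diels_alder_reaction(
    explicit_hydrogens: bool = False, validate: bool = True
) -> ReactionInstance:
    """The Diels-Alder example (hydrogen-suppressed by default).

    With ``validate`` the hydrogen-suppressed signature multisets must equal
    the published reference multisets, gating every use of this fixture on
    the faithfulness of the reconstruction.
    """
    if validate:
        check = parse_reaction(
            DIELS_ALDER_SMILES, explicit_hydrogens=False, reaction_id="diels-alder"
        )
        ref_i, ref_o = reference_diels_alder_multisets()
        got_i = signature_multiset(check.educts)
        got_o = signature_multiset(check.products)
        if got_i != ref_i or got_o != ref_o:
            raise FixtureError(
                "Diels-Alder reconstruction does not reproduce the reference "
                f"neighbourhood multisets: educts {got_i!r} vs {ref_i!r}, "
                f"products {got_o!r} vs {ref_o!r}"
            )
    return parse_reaction(
        DIELS_ALDER_SMILES,
        explicit_hydrogens=explicit_hydrogens,
        reaction_id="diels-alder",
    )


MEISENHEIMER_SMILES = "C=CC[N+](C)(C)[O-]>>C(ON(C)C)C=C"


def meisenheimer_reaction() -> ReactionInstance:
    """A [2,3]-Meisenheimer rearrangement, hydrogen-suppressed.

    The allylic shift breaks N-C, forms O-C at the far allyl terminus and
    shifts the double bond, while the N-O bond persists: a 5-cycle with an
    unchanging pseudo bond between the charged N+/O- pair.  No homovalent
    even alternating cycle exists for this reaction.
    """
    return parse_reaction(
        MEISENHEIMER_SMILES, explicit_hydrogens=False, reaction_id="meisenheimer"
    )


# ---------------------------------------------------------------------------
# planted-cycle generator
# ---------------------------------------------------------------------------

@dataclass
class PlantedReaction:
    reaction: ReactionInstance
    planted_map: AtomMap
    planted_candidate: ITSCandidate
    seed: int


_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}
_ELEMENTS = ["C", "C", "C", "N", "O"]  # sampling weights favour carbon


def _charged_vertex(d: int, rng: random.Random) -> tuple[str, int]:
    """Element/charge of an educt cycle vertex with lone-pair change d."""
    if d == 0:
        return rng.choice(_ELEMENTS), 0
    if d == 1:
        return "N", 1  # ammonium-like centre, neutralised by the reaction
    if d == -1:
        return "O", -1  # alkoxide-like centre, neutralised by the reaction
    raise FixtureError(f"cannot plant a lone-pair change of {d:+d}")


def _capacity(element: str, charge: int) -> int:
    base = _MAX_VALENCE[element]
    if charge > 0 and element in ("N", "O"):
        return base + charge
    return base + charge if charge < 0 else base


def plant_random_reaction(
    n_heavy: int,
    k: int,
    layout: ITSLayout,
    seed: int,
    max_retries: int = 50,
) -> PlantedReaction:
    """Plant ``layout`` (of size ``k``) inside a random reaction.

    Builds a random valence-respecting educt over C/N/O heavy atoms, wires
    the cycle's breaking/pseudo bonds in and keeps its forming pairs
    non-bonded, derives the product by applying the layout's bond and
    charge changes, completes hydrogens on both sides and returns the
    ground-truth atom map together with the planted candidate (normalised
    to the solver's symmetry-breaking convention).  Deterministic per seed.
    """
    if layout.k != k:
        raise FixtureError(f"layout has k={layout.k}, requested {k}")
    if n_heavy < k:
        raise FixtureError(f"need at least k={k} heavy atoms, got {n_heavy}")
    rng = random.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            return _plant_once(n_heavy, k, layout, rng, seed)
        except (FixtureError, ChemGraphError) as exc:
            last_err = exc
    raise FixtureError(
        f"no feasible planted reaction after {max_retries} retries: {last_err}"
    )


def _plant_once(
    n_heavy: int, k: int, layout: ITSLayout, rng: random.Random, seed: int
) -> PlantedReaction:
    cs, ds = layout.edge_changes, layout.vertex_lp_changes
    elements: list[str] = []
    charges_e: list[int] = []
    charges_p: list[int] = []
    for i in range(k):
        el, q = _charged_vertex(ds[i], rng)
        elements.append(el)
        charges_e.append(q)
        charges_p.append(q - ds[i])

    bonds_e: dict[tuple[int, int], int] = {}
    bonds_p: dict[tuple[int, int], int] = {}
    sum_e = [0] * n_heavy
    sum_p = [0] * n_heavy

    def add(bonds, sums, u, v, order):
        bonds[(min(u, v), max(u, v))] = order
        sums[u] += order
        sums[v] += order

    for i in range(k):
        j = (i + 1) % k
        c = cs[i]
        if c < 0:
            add(bonds_e, sum_e, i, j, -c)  # broken entirely in the product
        elif c == 0:
            add(bonds_e, sum_e, i, j, 1)
            add(bonds_p, sum_p, i, j, 1)
        else:
            add(bonds_p, sum_p, i, j, c)  # formed, absent in the educt

    # decorate with the remaining heavy atoms
    for v in range(k, n_heavy):
        elements.append(rng.choice(_ELEMENTS))
        charges_e.append(0)
        charges_p.append(0)
        cap_v = _MAX_VALENCE[elements[v]]
        hosts = [
            u
            for u in range(v)
            if min(
                _capacity(elements[u], charges_e[u]) - sum_e[u],
                _capacity(elements[u], charges_p[u]) - sum_p[u],
            )
            >= 1
        ]
        if not hosts or cap_v < 1:
            raise FixtureError("no attachment point with spare valence")
        u = rng.choice(hosts)
        order = 1
        if (
            rng.random() < 0.2
            and min(
                _capacity(elements[u], charges_e[u]) - sum_e[u],
                _capacity(elements[u], charges_p[u]) - sum_p[u],
            )
            >= 2
            and cap_v >= 2
        ):
            order = 2
        add(bonds_e, sum_e, u, v, order)
        add(bonds_p, sum_p, u, v, order)

    for v in range(n_heavy):
        if sum_e[v] > _capacity(elements[v], charges_e[v]):
            raise FixtureError("educt valence exceeded on the cycle")
        if sum_p[v] > _capacity(elements[v], charges_p[v]):
            raise FixtureError("product valence exceeded on the cycle")

    # random relabeling of educt atoms and an independent product permutation
    relab = list(range(n_heavy))
    rng.shuffle(relab)
    pi = list(range(n_heavy))
    rng.shuffle(pi)

    def build(elements, charges, bonds, label):
        atoms = [
            AtomNode(index=label[v], element=elements[v], formal_charge=charges[v])
            for v in range(n_heavy)
        ]
        atoms.sort(key=lambda a: a.index)
        remapped = {
            (min(label[u], label[v]), max(label[u], label[v])): o
            for (u, v), o in bonds.items()
        }
        return complete_hydrogens(MoleculeGraph(atoms, remapped))

    educts = build(elements, charges_e, bonds_e, relab)
    prod_label = [pi[relab[v]] for v in range(n_heavy)]
    products = build(elements, charges_p, bonds_p, prod_label)
    reaction = ReactionInstance(
        educts=educts, products=products, id=f"planted-{seed}"
    )

    # ground-truth map: heavy atoms via the permutation, hydrogens pairwise
    mapping = {v: pi[v] for v in range(n_heavy)}
    for v in range(n_heavy):
        hs_e = sorted(
            w for w in educts.adj[v] if educts.atoms[w].is_hydrogen
        )
        hs_p = sorted(
            w for w in products.adj[pi[v]] if products.atoms[w].is_hydrogen
        )
        if len(hs_e) != len(hs_p):
            raise FixtureError("hydrogen counts diverged between sides")
        mapping.update(zip(hs_e, hs_p))
    planted_map = AtomMap(mapping=mapping)

    candidate = _normalize_candidate(
        reaction,
        ITSCandidate(
            educt_cycle=tuple(relab[i] for i in range(k)),
            product_cycle=tuple(pi[relab[i]] for i in range(k)),
            layout=layout,
        ),
    )
    return PlantedReaction(
        reaction=reaction,
        planted_map=planted_map,
        planted_candidate=candidate,
        seed=seed,
    )


def _normalize_candidate(
    reaction: ReactionInstance, cand: ITSCandidate
) -> ITSCandidate:
    """Re-parameterise a cycle to the solver's symmetry-breaking form."""
    lay = cand.layout
    if not lay.rotation_symmetric:
        return cand
    k = lay.k
    lowest = min(cand.educt_cycle)
    for direction in (1, -1):
        for s in range(k):
            ec = tuple(cand.educt_cycle[(s + direction * t) % k] for t in range(k))
            if ec[0] != lowest:
                continue
            pc = tuple(cand.product_cycle[(s + direction * t) % k] for t in range(k))
            c2 = ITSCandidate(educt_cycle=ec, product_cycle=pc, layout=lay)
            ok, _ = check_candidate(reaction, c2, include_degree=False)
            if ok:
                return c2
    raise FixtureError("planted cycle admits no symmetry-normal form")
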