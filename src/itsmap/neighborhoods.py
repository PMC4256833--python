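"""Local neighbourhood signatures and multiset arithmetic.

The signature N(v) of an atom is its element label together with the
multiset of "order + neighbour label" strings over its incident bonds
(e.g. ``(C, <1C, 2C>)``).  Comparing the educt and product signature
multisets N_I and N_O yields, via occurrence-wise subtraction, the
neighbourhoods unique to one side — atoms that must take part in the
transition-state cycle — and from those a lower bound N^L on the element
labels the cycle has to contain.

Signatures are computed on whatever representation the graph carries:
explicit-hydrogen graphs include ``1H`` entries, hydrogen-suppressed
graphs do not.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .chem_graph import MoleculeGraph, ReactionInstance

__all__ = [
    "NeighborhoodSignature",
    "LabeledMultiset",
    "signature",
    "signature_multiset",
    "multiset_difference",
    "its_label_requirements",
    "sibling_hydrogen_removal",
]


@dataclass(frozen=True)
class NeighborhoodSignature:
    """Centre label plus one ``order⊕label`` entry per incident bond."""

    center_label: str
    edges: tuple[str, ...]  # canonically sorted

    def __str__(self) -> str:  # e.g. (C,<1C,2C>)
        return f"({self.center_label},<{','.join(self.edges)}>)"


class LabeledMultiset:
    """A multiset with occurrence function ``occ(x) >= 0``."""

    def __init__(self, items=()):
        self._counts = Counter(items)
        self._counts += Counter()  # drop zero/negative entries

    def occ(self, x) -> int:
        return self._counts.get(x, 0)

    def size(self) -> int:
        return sum(self._counts.values())

    def elements(self):
        return iter(self._counts)

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return self.size()

    def __iter__(self):
        return self._counts.elements()

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledMultiset):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self):
        return hash(frozenset(self._counts.items()))

    def __le__(self, other: "LabeledMultiset") -> bool:
        """Multiset inclusion: every occurrence covered by ``other``."""
        return all(other.occ(x) >= n for x, n in self._counts.items())

    def __repr__(self) -> str:
        parts = []
        for x, n in sorted(self._counts.items(), key=lambda kv: str(kv[0])):
            parts.append(f"{n}x{x}" if n > 1 else str(x))
        return f"<{', '.join(parts)}>"


def signature(graph: MoleculeGraph, v: int) -> NeighborhoodSignature:
    """N(v): centre label plus sorted incident ``order⊕label`` entries."""
    entries = sorted(
        f"{order}{graph.atoms[w].element}" for w, order in graph.adj[v].items()
    )
    return NeighborhoodSignature(graph.atoms[v].element, tuple(entries))


def signature_multiset(graph: MoleculeGraph) -> LabeledMultiset:
    """N_I (or N_O): the multiset of signatures over all vertices."""
    return LabeledMultiset(signature(graph, a.index) for a in graph.atoms)


def multiset_difference(a: LabeledMultiset, b: LabeledMultiset) -> LabeledMultiset:
    """Occurrence-wise subtraction: occ(x) -> max(0, occ_a(x) - occ_b(x))."""
    out = Counter()
    for x, n in a.items():
        keep = n - b.occ(x)
        if keep > 0:
            out[x] = keep
    return LabeledMultiset(out.elements())


def its_label_requirements(reaction: ReactionInstance) -> LabeledMultiset:
    """N^L: element labels of educt-unique neighbourhoods.

    A lower bound on the atom labels that must occur in the ITS cycle,
    computed on the same graph representation the search operates on.
    """
    n_i = signature_multiset(reaction.educts)
    n_o = signature_multiset(reaction.products)
    unique = multiset_difference(n_i, n_o)
    return LabeledMultiset(sig.center_label for sig in unique)


def sibling_hydrogen_removal(graph: MoleculeGraph) -> set[int]:
    """H_rem: non-master sibling hydrogens, excludable from search domains.

    For every atom with attached hydrogens the lowest-index hydrogen is the
    "master"; all other siblings are interchangeable by symmetry and are
    returned for domain removal.  A hydrogen is removed exactly when some
    lower-index hydrogen shares one of its bonding partners.
    """
    removed: set[int] = set()
    for a in graph.atoms:
        if a.is_hydrogen:
            continue
        hs = sorted(w for w in graph.adj[a.index] if graph.atoms[w].is_hydrogen)
        removed.update(hs[1:])
    return removed
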