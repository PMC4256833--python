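"""Molecular and reaction graph model with electron bookkeeping.

Educts and products of a reaction are each held as a single, possibly
disconnected, undirected graph.  Vertices are atoms labelled with their
element; edges carry integer bond orders (1-3).  Non-bonding electron
pairs live on the vertices (conceptually the diagonal of the adjacency
matrix) and are derived from element, formal charge and bond-order sum
rather than parsed, since SMILES carries no lone-pair field.

Two representations are supported:

* *explicit-hydrogen* graphs (the production representation): every
  hydrogen is a vertex, added by :func:`complete_hydrogens` according to
  a charge-adjusted standard-valence model;
* *hydrogen-suppressed* graphs: heavy atoms only, with the implicit
  hydrogen count recorded per atom.  Used for worked examples printed
  without hydrogens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomNode",
    "MoleculeGraph",
    "ReactionInstance",
    "AtomMap",
    "BalanceReport",
    "ChemGraphError",
    "SmilesParseError",
    "AromaticityError",
    "HypervalentError",
    "RadicalError",
    "ImbalanceError",
    "UnsupportedChemistryError",
    "parse_reaction",
    "parse_molecule",
    "complete_hydrogens",
    "lone_pairs",
    "standard_valence",
    "check_mass_balance",
    "reaction_matrix_rows",
    "write_mapped_smiles",
    "parse_mapped_reaction",
]


class ChemGraphError(ValueError):
    """Base error for reaction-graph construction."""


class SmilesParseError(ChemGraphError):
    pass


class AromaticityError(ChemGraphError):
    pass


class HypervalentError(ChemGraphError):
    pass


class RadicalError(ChemGraphError):
    pass


class ImbalanceError(ChemGraphError):
    pass


class UnsupportedChemistryError(ChemGraphError):
    pass


#: valence electrons per supported element (periodic group number)
VALENCE_ELECTRONS = {
    "H": 1,
    "C": 4,
    "N": 5,
    "O": 6,
    "F": 7,
    "P": 5,
    "S": 6,
    "Cl": 7,
    "Br": 7,
    "I": 7,
}

#: neutral standard valences; multi-valent elements list all allowed states
STANDARD_VALENCES = {
    "H": (1,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

#: elements whose cations gain one bonding site per unit charge
_CATION_ADJUSTABLE = {"N", "P", "O", "S"}


def _allowed_valences(element: str, charge: int) -> tuple[int, ...]:
    if element not in STANDARD_VALENCES:
        raise UnsupportedChemistryError(f"element {element!r} not supported")
    base = STANDARD_VALENCES[element]
    if charge == 0:
        return base
    if element == "H":
        raise UnsupportedChemistryError("charged hydrogen is not supported")
    if charge > 0 and element not in _CATION_ADJUSTABLE:
        raise UnsupportedChemistryError(
            f"cationic {element} is outside the supported valence model"
        )
    vals = tuple(v + charge for v in base if v + charge >= 0)
    if not vals:
        raise UnsupportedChemistryError(
            f"charge {charge:+d} on {element} leaves no valid valence"
        )
    return vals


def standard_valence(element: str, charge: int, bond_order_sum: int) -> int:
    """Smallest allowed (charge-adjusted) valence >= the current bond-order sum."""
    for v in _allowed_valences(element, charge):
        if v >= bond_order_sum:
            return v
    raise HypervalentError(
        f"hypervalent input: {element} (charge {charge:+d}) with bond-order "
        f"sum {bond_order_sum}"
    )


def lone_pairs(element: str, charge: int, bond_order_sum: int) -> int:
    """Non-bonding electron pairs of an atom.

    ``(valence_electrons - charge - bond_order_sum) / 2``, floored at zero.
    An odd remaining electron count indicates a radical, which the electron
    model does not cover.
    """
    if element not in VALENCE_ELECTRONS:
        raise UnsupportedChemistryError(f"element {element!r} not supported")
    n = VALENCE_ELECTRONS[element] - charge - bond_order_sum
    if n % 2 != 0:
        raise RadicalError(
            f"radical unsupported: {element} charge {charge:+d} with "
            f"bond-order sum {bond_order_sum} leaves an odd electron count"
        )
    return max(0, n // 2)


@dataclass(frozen=True)
class AtomNode:
    """A single atom vertex.

    ``implicit_h`` is nonzero only in hydrogen-suppressed graphs, where it
    records the hydrogens the atom would carry in the explicit representation.
    """

    index: int
    element: str
    formal_charge: int = 0
    lone_pairs: int = 0
    is_hydrogen: bool = False
    implicit_h: int = 0


class MoleculeGraph:
    """Undirected molecular graph with integer bond orders.

    Lone pairs are vertex attributes; there are no loop edges.
    """

    def __init__(self, atoms: list[AtomNode], bonds: dict[tuple[int, int], int]):
        self.atoms: list[AtomNode] = list(atoms)
        self.adj: dict[int, dict[int, int]] = {a.index: {} for a in self.atoms}
        for (u, v), order in bonds.items():
            self._add_bond(u, v, order)

    def _add_bond(self, u: int, v: int, order: int) -> None:
        if u == v:
            raise ChemGraphError("self-bonds are not allowed")
        if order not in (1, 2, 3):
            raise ChemGraphError(f"bond order must be 1, 2 or 3, got {order}")
        if v in self.adj[u]:
            raise ChemGraphError(f"duplicate bond between atoms {u} and {v}")
        self.adj[u][v] = order
        self.adj[v][u] = order

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def bonds(self) -> dict[tuple[int, int], int]:
        return {
            (u, v): o
            for u, nbrs in self.adj.items()
            for v, o in nbrs.items()
            if u < v
        }

    def order(self, u: int, v: int) -> int:
        return self.adj[u].get(v, 0)

    def degree(self, v: int) -> int:
        """Number of incident edges (distinct neighbours, loops excluded)."""
        return len(self.adj[v])

    def heavy_bond_order_sum(self, v: int) -> int:
        return sum(self.adj[v].values())

    def bond_order_sum(self, v: int) -> int:
        """Bond-order sum including implicit hydrogens (suppressed graphs)."""
        return self.heavy_bond_order_sum(v) + self.atoms[v].implicit_h

    def element_counts(self) -> Counter:
        c: Counter = Counter()
        for a in self.atoms:
            c[a.element] += 1
            if a.implicit_h:
                c["H"] += a.implicit_h
        return c

    def components(self) -> list[list[int]]:
        seen: set[int] = set()
        out: list[list[int]] = []
        for a in self.atoms:
            if a.index in seen:
                continue
            stack, comp = [a.index], []
            seen.add(a.index)
            while stack:
                u = stack.pop()
                comp.append(u)
                for w in self.adj[u]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            out.append(sorted(comp))
        return out

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(list(self.atoms), dict(self.bonds))


@dataclass
class ReactionInstance:
    """A reaction: educt graph I and product graph O."""

    educts: MoleculeGraph
    products: MoleculeGraph
    id: str | None = None


@dataclass
class AtomMap:
    """A bijection from educt vertices onto product vertices."""

    mapping: dict[int, int]

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.mapping.items()}

    def as_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.mapping.items()))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"syntax error while parsing SMILES {smiles!r}")
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    except Chem.KekulizeException as exc:
        raise AromaticityError(
            f"aromaticity unsupported: cannot kekulize {smiles!r}"
        ) from exc
    except Exception as exc:  # malformed valences etc.
        raise SmilesParseError(f"cannot sanitize SMILES {smiles!r}: {exc}") from exc
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:
        raise AromaticityError(
            f"aromaticity unsupported: cannot kekulize {smiles!r}"
        ) from exc
    return mol


def parse_molecule(
    smiles: str, explicit_hydrogens: bool = True
) -> MoleculeGraph:
    """Parse one side of a reaction (``.``-separated components).

    Atom ids follow SMILES parse order; with ``explicit_hydrogens`` the
    completed hydrogens are appended afterwards, grouped by their heavy-atom
    parent in parent order.
    """
    mol = _mol_from_smiles(smiles)
    atoms: list[AtomNode] = []
    for rd_atom in mol.GetAtoms():
        sym = rd_atom.GetSymbol()
        if sym not in STANDARD_VALENCES:
            raise UnsupportedChemistryError(f"element {sym!r} not supported")
        atoms.append(
            AtomNode(
                index=rd_atom.GetIdx(),
                element=sym,
                formal_charge=rd_atom.GetFormalCharge(),
                is_hydrogen=sym == "H",
            )
        )
    bonds: dict[tuple[int, int], int] = {}
    for b in mol.GetBonds():
        o = b.GetBondTypeAsDouble()
        if o not in (1.0, 2.0, 3.0):
            raise UnsupportedChemistryError(
                f"unsupported bond type {b.GetBondType()} in {smiles!r}"
            )
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds[(min(u, v), max(u, v))] = int(o)
    graph = MoleculeGraph(atoms, bonds)
    if explicit_hydrogens:
        return complete_hydrogens(graph)
    return _annotate_suppressed(graph)


def _annotate_suppressed(graph: MoleculeGraph) -> MoleculeGraph:
    """Record implicit hydrogen counts and lone pairs on a heavy-atom graph."""
    new_atoms = []
    for a in graph.atoms:
        s_heavy = graph.heavy_bond_order_sum(a.index)
        if a.is_hydrogen:
            h, full = 0, s_heavy
        else:
            val = standard_valence(a.element, a.formal_charge, s_heavy)
            h = val - s_heavy
            full = val
        lp = lone_pairs(a.element, a.formal_charge, full)
        new_atoms.append(replace(a, implicit_h=h, lone_pairs=lp))
    return MoleculeGraph(new_atoms, dict(graph.bonds))


def complete_hydrogens(graph: MoleculeGraph) -> MoleculeGraph:
    """Saturate every heavy atom to its charge-adjusted standard valence.

    Hydrogen vertices are appended after the parsed atoms, grouped by parent.
    Hydrogens already explicit in the input keep their parsed position.
    """
    atoms = list(graph.atoms)
    bonds = dict(graph.bonds)
    next_id = len(atoms)
    completed: list[AtomNode] = []
    for a in graph.atoms:
        s = graph.heavy_bond_order_sum(a.index)
        if a.is_hydrogen:
            if s > 1:
                raise HypervalentError("hydrogen with more than one bond")
            completed.append(replace(a, lone_pairs=lone_pairs("H", a.formal_charge, s)))
            continue
        val = standard_valence(a.element, a.formal_charge, s)
        n_add = val - s
        for _ in range(n_add):
            h = AtomNode(index=next_id, element="H", is_hydrogen=True)
            atoms.append(h)
            bonds[(a.index, next_id)] = 1
            next_id += 1
        lp = lone_pairs(a.element, a.formal_charge, val)
        completed.append(replace(a, lone_pairs=lp, implicit_h=0))
    completed.extend(atoms[len(graph.atoms):])
    return MoleculeGraph(completed, bonds)


def parse_reaction(
    text: str,
    explicit_hydrogens: bool = True,
    reaction_id: str | None = None,
    check_balance: bool = True,
) -> ReactionInstance:
    """Parse a reaction SMILES ``educts>>products`` into a ReactionInstance."""
    if ">>" not in text:
        raise SmilesParseError(f"reaction SMILES must contain '>>': {text!r}")
    left, _, right = text.partition(">>")
    educts = parse_molecule(left, explicit_hydrogens)
    products = parse_molecule(right, explicit_hydrogens)
    rxn = ReactionInstance(educts=educts, products=products, id=reaction_id)
    if check_balance:
        report = check_mass_balance(rxn)
        if not report.balanced:
            raise ImbalanceError(f"mass imbalance in {text!r}: {report.describe()}")
    return rxn


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    balanced: bool
    size_educts: int
    size_products: int
    element_deltas: dict[str, int] = field(default_factory=dict)

    def describe(self) -> str:
        if self.balanced:
            return "balanced"
        parts = []
        if self.size_educts != self.size_products:
            parts.append(
                f"atom counts differ ({self.size_educts} vs {self.size_products})"
            )
        if self.element_deltas:
            delta = ", ".join(
                f"{el}: {d:+d}" for el, d in sorted(self.element_deltas.items())
            )
            parts.append(f"element deltas {{{delta}}}")
        return "; ".join(parts)


def check_mass_balance(reaction: ReactionInstance) -> BalanceReport:
    """No atom may appear or vanish: sizes and element multisets must match."""
    ce = reaction.educts.element_counts()
    cp = reaction.products.element_counts()
    deltas = {
        el: ce.get(el, 0) - cp.get(el, 0)
        for el in set(ce) | set(cp)
        if ce.get(el, 0) != cp.get(el, 0)
    }
    n_e = sum(ce.values())
    n_p = sum(cp.values())
    return BalanceReport(
        balanced=not deltas and n_e == n_p,
        size_educts=n_e,
        size_products=n_p,
        element_deltas=deltas,
    )


def reaction_matrix_rows(
    reaction: ReactionInstance, mapping: dict[int, int]
) -> dict[int, dict]:
    """Per-educt-vertex rows of the reaction matrix O - (I o m).

    Each row records the bond-order change towards every educt neighbour or
    new product partner, plus the lone-pair (diagonal) change.  For a valid
    atom map every row sums to zero.
    """
    I, O = reaction.educts, reaction.products
    inv = {v: k for k, v in mapping.items()}
    rows: dict[int, dict] = {}
    for x, mx in mapping.items():
        changes: dict[int, int] = {}
        partners = set(I.adj[x]) | {inv[w] for w in O.adj[mx] if w in inv}
        for y in partners:
            d = O.order(mx, mapping[y]) - I.order(x, y)
            if d != 0:
                changes[y] = d
        lp_change = O.atoms[mx].lone_pairs - I.atoms[x].lone_pairs
        rows[x] = {
            "bond_changes": changes,
            "lone_pair_change": lp_change,
            "row_sum": sum(changes.values()) + lp_change,
        }
    return rows


# ---------------------------------------------------------------------------
# mapped SMILES I/O
# ---------------------------------------------------------------------------

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _graph_to_mol(graph: MoleculeGraph, map_numbers: dict[int, int]) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in graph.atoms:
        rd = Chem.Atom(a.element)
        rd.SetFormalCharge(a.formal_charge)
        rd.SetNoImplicit(a.implicit_h == 0)
        if a.implicit_h:
            rd.SetNumExplicitHs(a.implicit_h)
        if a.index in map_numbers:
            rd.SetAtomMapNum(map_numbers[a.index])
        rw.AddAtom(rd)
    for (u, v), o in graph.bonds.items():
        rw.AddBond(u, v, _BOND_TYPES[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(
        mol,
        Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
    )
    return mol


def write_mapped_smiles(reaction: ReactionInstance, amap: AtomMap) -> str:
    """Annotated reaction SMILES with ``:n`` atom-map classes.

    Educt atom ``x`` and its image ``m(x)`` share the class ``x + 1``; each
    class therefore occurs exactly once on either side.  The map must pass
    :func:`itsmap.map_extension.verify_atom_map` first.
    """
    from .map_extension import verify_atom_map  # local import: avoid cycle

    ok, violations = verify_atom_map(reaction, amap)
    if not ok:
        raise ChemGraphError(
            f"refusing to write an unverified atom map: {violations}"
        )
    educt_classes = {x: x + 1 for x in range(len(reaction.educts))}
    product_classes = {amap.mapping[x]: x + 1 for x in range(len(reaction.educts))}
    mol_e = _graph_to_mol(reaction.educts, educt_classes)
    mol_p = _graph_to_mol(reaction.products, product_classes)
    left = Chem.MolToSmiles(mol_e, canonical=False)
    right = Chem.MolToSmiles(mol_p, canonical=False)
    return f"{left}>>{right}"


def parse_mapped_reaction(
    text: str, explicit_hydrogens: bool = True
) -> tuple[ReactionInstance, AtomMap]:
    """Parse an atom-map-annotated reaction SMILES and recover its bijection."""
    if ">>" not in text:
        raise SmilesParseError(f"reaction SMILES must contain '>>': {text!r}")
    left, _, right = text.partition(">>")

    def side_classes(smiles: str) -> dict[int, int]:
        mol = _mol_from_smiles(smiles)
        return {
            a.GetIdx(): a.GetAtomMapNum()
            for a in mol.GetAtoms()
            if a.GetAtomMapNum() > 0
        }

    ec = side_classes(left)
    pc = side_classes(right)
    rxn = parse_reaction(text, explicit_hydrogens=explicit_hydrogens)
    by_class_p: dict[int, int] = {}
    for idx, cls in pc.items():
        if cls in by_class_p:
            raise ChemGraphError(f"atom-map class {cls} repeated among products")
        by_class_p[cls] = idx
    if sorted(ec.values()) != sorted(by_class_p):
        raise ChemGraphError("educt and product atom-map classes do not match")
    mapping = {idx: by_class_p[cls] for idx, cls in ec.items()}
    return rxn, AtomMap(mapping=mapping)
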