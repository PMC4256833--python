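"""Finite-domain CSP search for cyclic ITS candidates.

For a cycle layout of size ``k`` the model carries ``k`` variables
``X^I_i`` over educt vertices and ``k`` variables ``X^O_i`` over product
vertices.  A solution assigns the ordered educt cycle and its product
image such that

* each side is assigned pairwise-distinct vertices,
* paired vertices agree in element label,
* the lone-pair difference at position ``i`` equals the layout's ``d_i``,
* paired vertices differ by at most one incident edge,
* every consecutive cycle pair realises the layout's bond-order change
  ``c_i`` (0-change pseudo bonds must exist unchanged on both sides), and
* for rotation-symmetric layouts, ``X^I_1`` is the smallest educt cycle
  vertex (symmetry breaking; the cycle direction is anchored by the
  breaking first edge).

The *extended* model additionally prunes non-master sibling hydrogens
from all domains, enforces label cardinalities derived from the
educt-unique neighbourhood multiset, and re-checks the unique
neighbourhoods on complete assignments.

Search is depth-first with constraint propagation to a fixpoint after
every assignment; branching picks the variable with the smallest current
domain and tries non-hydrogen vertices (ascending id) before hydrogens.
A declarative generate-and-test oracle, independent of the propagation
engine, is provided for cross-checking on small inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .chem_graph import MoleculeGraph, ReactionInstance, check_mass_balance
from .its_layouts import ITSLayout
from .neighborhoods import (
    multiset_difference,
    sibling_hydrogen_removal,
    signature,
    signature_multiset,
)

__all__ = [
    "ITSModel",
    "ITSCandidate",
    "ModelError",
    "build_model",
    "enumerate_candidates",
    "first_candidate",
    "brute_force_candidates",
    "check_candidate",
]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ITSCandidate:
    """An ordered educt cycle paired with its product image."""

    educt_cycle: tuple[int, ...]
    product_cycle: tuple[int, ...]
    layout: ITSLayout

    @property
    def k(self) -> int:
        return self.layout.k

    def pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.educt_cycle, self.product_cycle))


def _degree(graph: MoleculeGraph, v: int, mode: str) -> int:
    if mode == "edges":
        return graph.degree(v)
    if mode == "bond_order_sum":
        return graph.bond_order_sum(v)
    raise ModelError(f"unknown degree mode {mode!r}")


@dataclass
class ITSModel:
    """A built (rooted) model: reaction, layout and initial domains."""

    reaction: ReactionInstance
    layout: ITSLayout
    mode: str = "basic"  # basic | extended
    symmetry_breaking: bool = True
    degree_mode: str = "edges"  # edges | bond_order_sum

    # derived, filled by build_model
    domains_i: list[set[int]] = field(default_factory=list)
    domains_o: list[set[int]] = field(default_factory=list)
    h_rem_i: set[int] = field(default_factory=set)
    h_rem_o: set[int] = field(default_factory=set)
    label_requirements: Counter = field(default_factory=Counter)
    educt_unique: Counter = field(default_factory=Counter)
    product_unique: Counter = field(default_factory=Counter)

    @property
    def k(self) -> int:
        return self.layout.k

    @property
    def infeasible(self) -> bool:
        return any(not d for d in self.domains_i + self.domains_o)


def build_model(
    reaction: ReactionInstance,
    layout: ITSLayout,
    mode: str = "basic",
    symmetry_breaking: bool = True,
    degree_mode: str = "edges",
) -> ITSModel:
    """Construct the CSP model and perform root-level domain reduction."""
    if mode not in ("basic", "extended"):
        raise ModelError(f"unknown mode {mode!r}")
    report = check_mass_balance(reaction)
    if not report.balanced:
        raise ModelError(f"reaction is not mass-balanced: {report.describe()}")

    model = ITSModel(
        reaction=reaction,
        layout=layout,
        mode=mode,
        symmetry_breaking=symmetry_breaking,
        degree_mode=degree_mode,
    )
    I, O = reaction.educts, reaction.products
    k = layout.k
    v_i = {a.index for a in I.atoms}
    v_o = {a.index for a in O.atoms}

    if mode == "extended":
        model.h_rem_i = sibling_hydrogen_removal(I)
        model.h_rem_o = sibling_hydrogen_removal(O)
        v_i = v_i - model.h_rem_i
        v_o = v_o - model.h_rem_o

        n_i = signature_multiset(I)
        n_o = signature_multiset(O)
        model.educt_unique = Counter(dict(multiset_difference(n_i, n_o).items()))
        model.product_unique = Counter(dict(multiset_difference(n_o, n_i).items()))
        model.label_requirements = Counter(
            sig.center_label for sig in model.educt_unique.elements()
        )

    # root arc consistency for the paired label/lone-pair/degree constraint
    by_key_o: dict[tuple, list[int]] = {}
    for b in sorted(v_o):
        key = (O.atoms[b].element, O.atoms[b].lone_pairs, _degree(O, b, degree_mode))
        by_key_o.setdefault(key, []).append(b)

    for i in range(k):
        d = layout.vertex_lp_changes[i]
        dom_i, dom_o = set(), set()
        for a in v_i:
            la = I.atoms[a].element
            lp_a = I.atoms[a].lone_pairs
            deg_a = _degree(I, a, degree_mode)
            lp_b = lp_a + d
            if lp_b < 0:
                continue
            for (lb, lpb, degb), bs in by_key_o.items():
                if lb == la and lpb == lp_b and abs(deg_a - degb) <= 1:
                    dom_i.add(a)
                    dom_o.update(bs)
        model.domains_i.append(dom_i)
        model.domains_o.append(dom_o)

    if mode == "extended":
        labels_avail = Counter()
        for dom in model.domains_i:
            for lab in {I.atoms[a].element for a in dom}:
                labels_avail[lab] += 1
        for lab, need in model.label_requirements.items():
            if labels_avail.get(lab, 0) < need:
                # a required label cannot be realised: immediately infeasible
                model.domains_i = [set() for _ in range(k)]
                model.domains_o = [set() for _ in range(k)]
                break
    return model


# ---------------------------------------------------------------------------
# the propagation/search engine
# ---------------------------------------------------------------------------

class _Solver:
    """Trail-based DFS with per-constraint domain filtering."""

    def __init__(self, model: ITSModel):
        self.model = model
        self.k = k = model.k
        I, O = model.reaction.educts, model.reaction.products
        self.I, self.O = I, O
        self.adj_i = I.adj
        self.adj_o = O.adj
        self.is_h_i = [a.is_hydrogen for a in I.atoms]
        self.is_h_o = [a.is_hydrogen for a in O.atoms]
        # vars: 0..k-1 educt side, k..2k-1 product side
        self.domains: list[set[int]] = [set(d) for d in model.domains_i] + [
            set(d) for d in model.domains_o
        ]
        self.trail: list[tuple[int, set[int]]] = []

        dm = model.degree_mode
        self.pair_ok: list[dict[int, set[int]]] = []
        self.pair_ok_rev: list[dict[int, set[int]]] = []
        for i in range(k):
            d = model.layout.vertex_lp_changes[i]
            fwd: dict[int, set[int]] = {}
            rev: dict[int, set[int]] = {}
            for a in self.domains[i]:
                la, lpa = I.atoms[a].element, I.atoms[a].lone_pairs
                dega = _degree(I, a, dm)
                supp = {
                    b
                    for b in self.domains[k + i]
                    if O.atoms[b].element == la
                    and O.atoms[b].lone_pairs == lpa + d
                    and abs(dega - _degree(O, b, dm)) <= 1
                }
                fwd[a] = supp
                for b in supp:
                    rev.setdefault(b, set()).add(a)
            self.pair_ok.append(fwd)
            self.pair_ok_rev.append(rev)

        # constraint incidence: var -> list of cycle-edge constraint ids
        self.cycle_cons = [
            (i, (i + 1) % k, model.layout.edge_changes[i]) for i in range(k)
        ]
        self.cons_of_var: list[list[int]] = [[] for _ in range(2 * k)]
        for ci, (i, j, _c) in enumerate(self.cycle_cons):
            for var in (i, j, k + i, k + j):
                self.cons_of_var[var].append(ci)

        self.symmetry = model.symmetry_breaking and model.layout.rotation_symmetric
        if model.mode == "extended":
            self.atoms_by_label_i: dict[str, set[int]] = {}
            for a in I.atoms:
                self.atoms_by_label_i.setdefault(a.element, set()).add(a.index)
            self.sig_i = {a.index: signature(I, a.index) for a in I.atoms}
            self.sig_o = {a.index: signature(O, a.index) for a in O.atoms}

    # -- trail helpers -----------------------------------------------------
    def _remove(self, var: int, values: set[int], queue: list[int]) -> bool:
        dom = self.domains[var]
        removed = dom & values
        if not removed:
            return True
        dom -= removed
        self.trail.append((var, removed))
        if not dom:
            return False
        queue.append(var)
        return True

    def _restrict(self, var: int, allowed, queue: list[int]) -> bool:
        dom = self.domains[var]
        removed = {x for x in dom if x not in allowed}
        if not removed:
            return True
        dom -= removed
        self.trail.append((var, removed))
        if not dom:
            return False
        queue.append(var)
        return True

    def _undo(self, mark: int) -> None:
        while len(self.trail) > mark:
            var, removed = self.trail.pop()
            self.domains[var] |= removed

    # -- propagation -------------------------------------------------------
    def _apply_pair(self, i: int, queue: list[int]) -> bool:
        k = self.k
        di, do = self.domains[i], self.domains[k + i]
        if len(di) == 1:
            (a,) = di
            return self._restrict(k + i, self.pair_ok[i].get(a, ()), queue)
        if len(do) == 1:
            (b,) = do
            return self._restrict(i, self.pair_ok_rev[i].get(b, ()), queue)
        return True

    def _apply_cycle(self, ci: int, queue: list[int]) -> bool:
        k = self.k
        i, j, c = self.cycle_cons[ci]
        dii, dij = self.domains[i], self.domains[j]
        doi, doj = self.domains[k + i], self.domains[k + j]
        adj_i, adj_o = self.adj_i, self.adj_o

        need_i = max(1, -c) if c <= 0 else 0
        need_o = max(1, c) if c >= 0 else 0
        if need_i:
            if len(dii) == 1:
                (a,) = dii
                ok = self._restrict(
                    j, {w for w, o in adj_i[a].items() if o >= need_i}, queue
                )
                if not ok:
                    return False
                dij = self.domains[j]
            if len(dij) == 1:
                (aj,) = dij
                if not self._restrict(
                    i, {w for w, o in adj_i[aj].items() if o >= need_i}, queue
                ):
                    return False
        if need_o:
            if len(doi) == 1:
                (b,) = doi
                ok = self._restrict(
                    k + j, {w for w, o in adj_o[b].items() if o >= need_o}, queue
                )
                if not ok:
                    return False
                doj = self.domains[k + j]
            if len(doj) == 1:
                (bj,) = doj
                if not self._restrict(
                    k + i, {w for w, o in adj_o[bj].items() if o >= need_o}, queue
                ):
                    return False

        dii, dij = self.domains[i], self.domains[j]
        doi, doj = self.domains[k + i], self.domains[k + j]
        if len(dii) == 1 and len(dij) == 1:
            (a,) = dii
            (aj,) = dij
            target = adj_i[a].get(aj, 0) + c
            if target < 0 or target > 3:
                return False
            if len(doi) == 1:
                (b,) = doi
                allowed = {w for w in doj if adj_o[b].get(w, 0) == target}
                if not self._restrict(k + j, allowed, queue):
                    return False
            elif len(doj) == 1:
                (bj,) = doj
                allowed = {w for w in doi if adj_o[bj].get(w, 0) == target}
                if not self._restrict(k + i, allowed, queue):
                    return False
        doi, doj = self.domains[k + i], self.domains[k + j]
        if len(doi) == 1 and len(doj) == 1:
            (b,) = doi
            (bj,) = doj
            target = adj_o[b].get(bj, 0) - c
            if target < 0 or target > 3:
                return False
            dii, dij = self.domains[i], self.domains[j]
            if len(dii) == 1:
                (a,) = dii
                allowed = {w for w in dij if adj_i[a].get(w, 0) == target}
                if not self._restrict(j, allowed, queue):
                    return False
            elif len(dij) == 1:
                (aj,) = dij
                allowed = {w for w in dii if adj_i[aj].get(w, 0) == target}
                if not self._restrict(i, allowed, queue):
                    return False
        return True

    def _propagate(self, queue: list[int]) -> bool:
        k = self.k
        while queue:
            var = queue.pop()
            dom = self.domains[var]
            if len(dom) == 1:
                (val,) = dom
                # all-different on the same side
                side = range(k) if var < k else range(k, 2 * k)
                for other in side:
                    if other != var and val in self.domains[other]:
                        if not self._remove(other, {val}, queue):
                            return False
                # symmetry breaking: X^I_1 strictly smallest on the educt side
                if self.symmetry and var < k:
                    if var == 0:
                        for other in range(1, k):
                            bad = {x for x in self.domains[other] if x <= val}
                            if bad and not self._remove(other, bad, queue):
                                return False
                    else:
                        bad = {x for x in self.domains[0] if x >= val}
                        if bad and not self._remove(0, bad, queue):
                            return False
            pi = var if var < k else var - k
            if not self._apply_pair(pi, queue):
                return False
            for ci in self.cons_of_var[var]:
                if not self._apply_cycle(ci, queue):
                    return False
        if self.model.mode == "extended":
            return self._check_cardinality()
        return True

    def _check_cardinality(self) -> bool:
        # lower bound: enough educt variables can still take each required label
        for lab, need in self.model.label_requirements.items():
            atoms = self.atoms_by_label_i.get(lab)
            if atoms is None:
                return False
            possible = sum(
                1 for i in range(self.k) if not self.domains[i].isdisjoint(atoms)
            )
            if possible < need:
                return False
        return True

    def _leaf_ok(self) -> bool:
        if self.model.mode != "extended":
            return True
        educt = [next(iter(self.domains[i])) for i in range(self.k)]
        prod = [next(iter(self.domains[self.k + i])) for i in range(self.k)]
        sig_e = Counter(self.sig_i[a] for a in educt)
        for sig, n in self.model.educt_unique.items():
            if sig_e.get(sig, 0) < n:
                return False
        sig_p = Counter(self.sig_o[b] for b in prod)
        for sig, n in self.model.product_unique.items():
            if sig_p.get(sig, 0) < n:
                return False
        return True

    # -- search ------------------------------------------------------------
    def solve(self, limit: int | None = None) -> list[ITSCandidate]:
        out: list[ITSCandidate] = []
        queue = list(range(2 * self.k))
        mark = len(self.trail)
        if self._propagate(queue):
            self._search(out, limit)
        self._undo(mark)
        return out

    def _search(self, out: list[ITSCandidate], limit: int | None) -> bool:
        k = self.k
        best, best_size = -1, None
        for var in range(2 * k):
            size = len(self.domains[var])
            if size > 1 and (best_size is None or size < best_size):
                best, best_size = var, size
        if best < 0:
            if self._leaf_ok():
                out.append(
                    ITSCandidate(
                        educt_cycle=tuple(
                            next(iter(self.domains[i])) for i in range(k)
                        ),
                        product_cycle=tuple(
                            next(iter(self.domains[k + i])) for i in range(k)
                        ),
                        layout=self.model.layout,
                    )
                )
                if limit is not None and len(out) >= limit:
                    return False
            return True

        is_h = self.is_h_i if best < k else self.is_h_o
        values = sorted(self.domains[best], key=lambda v: (is_h[v], v))
        for val in values:
            mark = len(self.trail)
            dom = self.domains[best]
            removed = dom - {val}
            dom -= removed
            self.trail.append((best, removed))
            if self._propagate([best]):
                if not self._search(out, limit):
                    self._undo(mark)
                    return False
            self._undo(mark)
        return True


def enumerate_candidates(
    model: ITSModel, limit: int | None = None
) -> list[ITSCandidate]:
    """All assignments satisfying the model, in deterministic search order."""
    if model.infeasible:
        return []
    return _Solver(model).solve(limit=limit)


def first_candidate(model: ITSModel) -> ITSCandidate | None:
    """First solution of the same search, or ``None`` if infeasible."""
    sols = enumerate_candidates(model, limit=1)
    return sols[0] if sols else None


# ---------------------------------------------------------------------------
# independent oracle and candidate checking
# ---------------------------------------------------------------------------

def check_candidate(
    reaction: ReactionInstance,
    candidate: ITSCandidate,
    degree_mode: str = "edges",
    include_degree: bool = True,
) -> tuple[bool, list[str]]:
    """Re-check a candidate against its defining conditions, solver-free."""
    I, O = reaction.educts, reaction.products
    lay = candidate.layout
    k = lay.k
    ec, pc = candidate.educt_cycle, candidate.product_cycle
    errs: list[str] = []
    if len(set(ec)) != k or len(set(pc)) != k:
        errs.append("cycle vertices are not pairwise distinct")
    for i in range(k):
        a, b = ec[i], pc[i]
        if I.atoms[a].element != O.atoms[b].element:
            errs.append(f"position {i + 1}: element mismatch")
        if O.atoms[b].lone_pairs - I.atoms[a].lone_pairs != lay.vertex_lp_changes[i]:
            errs.append(f"position {i + 1}: lone-pair change mismatch")
        if include_degree and abs(
            _degree(I, a, degree_mode) - _degree(O, b, degree_mode)
        ) > 1:
            errs.append(f"position {i + 1}: degree difference > 1")
    for i in range(k):
        j = (i + 1) % k
        c = lay.edge_changes[i]
        oi = I.order(ec[i], ec[j])
        oo = O.order(pc[i], pc[j])
        if oo - oi != c:
            errs.append(f"edge {i + 1}: change {oo} - {oi} != {c}")
        if c == 0 and oi < 1:
            errs.append(f"edge {i + 1}: pseudo bond absent")
    return not errs, errs


def brute_force_candidates(
    reaction: ReactionInstance,
    layout: ITSLayout,
    symmetry_breaking: bool = True,
    degree_mode: str = "edges",
    max_atoms: int = 16,
) -> list[ITSCandidate]:
    """Exhaustive generate-and-test over ordered vertex tuples.

    Declarative restatement of the model used as a testing oracle: no
    domains, no propagation — plain depth-first enumeration with incremental
    feasibility checks.  Guarded to small inputs.
    """
    I, O = reaction.educts, reaction.products
    n = len(I)
    if n > max_atoms:
        raise ModelError(
            f"oracle guard: {n} educt atoms > {max_atoms}; raise max_atoms to override"
        )
    k = layout.k
    cs = layout.edge_changes
    ds = layout.vertex_lp_changes
    apply_symmetry = symmetry_breaking and layout.rotation_symmetric
    out: list[ITSCandidate] = []
    v_i = [a.index for a in I.atoms]
    v_o = [a.index for a in O.atoms]

    def educt_ok(tup: tuple[int, ...], closed: bool) -> bool:
        m = len(tup)
        for i in range(m - 1):
            c = cs[i]
            if c <= 0 and I.order(tup[i], tup[i + 1]) < max(1, -c):
                return False
        if closed and cs[k - 1] <= 0:
            if I.order(tup[-1], tup[0]) < max(1, -cs[k - 1]):
                return False
        if apply_symmetry and m > 1 and min(tup) != tup[0]:
            return False
        return True

    def product_ok(etup, ptup, closed: bool) -> bool:
        m = len(ptup)
        for i in range(m):
            a, b = etup[i], ptup[i]
            if I.atoms[a].element != O.atoms[b].element:
                return False
            if O.atoms[b].lone_pairs - I.atoms[a].lone_pairs != ds[i]:
                return False
            if abs(_degree(I, a, degree_mode) - _degree(O, b, degree_mode)) > 1:
                return False
        for i in range(m - 1):
            if O.order(ptup[i], ptup[i + 1]) - I.order(etup[i], etup[i + 1]) != cs[i]:
                return False
        if closed:
            if O.order(ptup[-1], ptup[0]) - I.order(etup[-1], etup[0]) != cs[k - 1]:
                return False
        return True

    def extend_product(etup, ptup):
        if len(ptup) == k:
            if product_ok(etup, ptup, closed=True):
                out.append(
                    ITSCandidate(
                        educt_cycle=etup, product_cycle=ptup, layout=layout
                    )
                )
            return
        for b in v_o:
            if b in ptup:
                continue
            cand = ptup + (b,)
            if product_ok(etup, cand, closed=False):
                extend_product(etup, cand)

    def extend_educt(tup):
        if len(tup) == k:
            if educt_ok(tup, closed=True):
                extend_product(tup, ())
            return
        for a in v_i:
            if a in tup:
                continue
            cand = tup + (a,)
            if educt_ok(cand, closed=False):
                extend_educt(cand)

    extend_educt(())
    return out
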