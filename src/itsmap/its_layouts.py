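"""Catalog of cyclic imaginary-transition-state (ITS) layouts.

A layout describes, around a cycle of ``k`` atoms, the bond-order change
``c_i`` on each cycle edge ``(i, i+1)`` (with ``c_k`` closing the cycle)
and the lone-pair change ``d_i`` at each vertex.  Electron conservation
requires ``c_{i-1} + c_i + d_i = 0`` at every vertex: a broken bond is
compensated by a formed bond or by a gained lone pair.

Homovalent elementary reactions (no oxidation-state change anywhere) have
even alternating cycles, ``c = (-1, +1, ..., -1, +1)`` and ``d = 0``.
Ambivalent reactions admit odd cycles: either two oppositely charged
atoms joined by an unchanging *pseudo bond* (a 0-change edge that must
exist with equal positive order on both sides), or a single atom whose
lone-pair count changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "ITSLayout",
    "LayoutCatalog",
    "LayoutError",
    "homovalent_cycle",
    "default_catalog",
    "validate_layout",
    "load_catalog",
    "dump_catalog",
]


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class ITSLayout:
    name: str
    k: int
    edge_changes: tuple[int, ...]  # c_1..c_k; c_i on edge (i, i+1), c_k closes
    vertex_lp_changes: tuple[int, ...]  # d_1..d_k

    @property
    def homovalent(self) -> bool:
        return all(d == 0 for d in self.vertex_lp_changes)

    def rotation_period(self) -> int:
        """Smallest cyclic shift mapping the layout onto itself."""
        k = self.k
        seq = list(zip(self.edge_changes, self.vertex_lp_changes))
        for p in range(1, k + 1):
            if k % p:
                continue
            if all(
                seq[i] == seq[(i + p) % k]
                and self.vertex_lp_changes[i] == self.vertex_lp_changes[(i + p) % k]
                for i in range(k)
            ):
                return p
        return k

    @property
    def rotation_symmetric(self) -> bool:
        return self.rotation_period() < self.k


def validate_layout(layout: ITSLayout) -> tuple[bool, list[str]]:
    """Check per-vertex electron balance and the nonzero-edge requirement."""
    violations: list[str] = []
    k = layout.k
    if k < 3:
        violations.append(f"cycle length {k} < 3")
    if len(layout.edge_changes) != k or len(layout.vertex_lp_changes) != k:
        violations.append("edge/vertex change lists must have length k")
        return False, violations
    if all(c == 0 for c in layout.edge_changes):
        violations.append("at least one edge must change")
    for i in range(k):
        c_prev = layout.edge_changes[i - 1]  # c_0 == c_k by cyclic indexing
        c_here = layout.edge_changes[i]
        d = layout.vertex_lp_changes[i]
        if c_prev + c_here + d != 0:
            violations.append(
                f"vertex {i + 1}: {c_prev} + {c_here} + {d} != 0"
            )
    return not violations, violations


def homovalent_cycle(k: int, name: str | None = None) -> ITSLayout:
    """Even alternating cycle: odd-position edges break, even-position form."""
    if k % 2 or k < 4:
        raise LayoutError(
            f"homovalent ITS cycles need an even number of atoms >= 4, got {k}"
        )
    edges = tuple(-1 if i % 2 == 0 else 1 for i in range(k))
    return ITSLayout(
        name=name or f"homovalent-{k}",
        k=k,
        edge_changes=edges,
        vertex_lp_changes=(0,) * k,
    )


def _pseudo_bond_cycle(k: int, invert: bool = False) -> ITSLayout:
    """Odd cycle: alternating path closed by an unchanging pseudo bond.

    The pseudo-bond endpoints carry opposite lone-pair changes (the pair of
    oppositely charged atoms, e.g. N+ / O-).  ``invert`` flips all signs.
    """
    if k % 2 == 0 or k < 3:
        raise LayoutError(f"pseudo-bond layouts need an odd cycle >= 3, got {k}")
    edges = [-1 if i % 2 == 0 else 1 for i in range(k - 1)] + [0]
    d = [0] * k
    d[0] = 1  # loses the broken bond, gains a lone pair
    d[-1] = -1  # gains the formed bond, loses a lone pair
    if invert:
        edges = [-c for c in edges]
        d = [-x for x in d]
    suffix = "-inv" if invert else ""
    return ITSLayout(
        name=f"ambivalent-pseudo-{k}{suffix}",
        k=k,
        edge_changes=tuple(edges),
        vertex_lp_changes=tuple(d),
    )


def _oxidation_cycle(k: int, invert: bool = False) -> ITSLayout:
    """Odd cycle, every edge changing, one atom absorbing the imbalance.

    With unit edge changes an odd cycle cannot alternate everywhere; the
    single defect vertex changes its lone-pair count by two (one oxidation
    state step of two electrons).
    """
    if k % 2 == 0 or k < 3:
        raise LayoutError(f"oxidation-state layouts need an odd cycle >= 3, got {k}")
    edges = [-1 if i % 2 == 0 else 1 for i in range(k - 1)] + [-1]
    d = [0] * k
    d[0] = 2  # c_k = -1 and c_1 = -1 meet here
    if invert:
        edges = [-c for c in edges]
        d = [-x for x in d]
    suffix = "-inv" if invert else ""
    return ITSLayout(
        name=f"ambivalent-oxstate-{k}{suffix}",
        k=k,
        edge_changes=tuple(edges),
        vertex_lp_changes=tuple(d),
    )


class LayoutCatalog:
    """Named collection of validated layouts."""

    def __init__(self, layouts=()):
        self._layouts: dict[str, ITSLayout] = {}
        for lay in layouts:
            self.add(lay)

    def add(self, layout: ITSLayout) -> None:
        ok, violations = validate_layout(layout)
        if not ok:
            raise LayoutError(f"invalid layout {layout.name!r}: {violations}")
        self._layouts[layout.name] = layout

    def __iter__(self):
        return iter(self._layouts.values())

    def __len__(self):
        return len(self._layouts)

    def __contains__(self, name: str) -> bool:
        return name in self._layouts

    def get(self, name: str) -> ITSLayout:
        try:
            return self._layouts[name]
        except KeyError:
            raise LayoutError(f"unknown layout {name!r}") from None

    def names(self) -> list[str]:
        return list(self._layouts)

    def homovalent(self) -> list[ITSLayout]:
        return [lay for lay in self if lay.homovalent]

    def ambivalent(self) -> list[ITSLayout]:
        return [lay for lay in self if not lay.homovalent]


def default_catalog() -> LayoutCatalog:
    """The shipped layout catalog.

    Homovalent alternating cycles for k in {4, 6, 8} plus the odd-cycle
    ambivalent patterns (pseudo-bond pair and single oxidation-state change,
    each with its sign-inverted variant) for k in {3, 5, 7}.  The catalog is
    config-extensible via :func:`load_catalog` and not claimed exhaustive.
    """
    cat = LayoutCatalog()
    for k in (4, 6, 8):
        cat.add(homovalent_cycle(k))
    for k in (3, 5, 7):
        cat.add(_pseudo_bond_cycle(k))
        cat.add(_pseudo_bond_cycle(k, invert=True))
        cat.add(_oxidation_cycle(k))
        cat.add(_oxidation_cycle(k, invert=True))
    return cat


def load_catalog(path) -> LayoutCatalog:
    """Load a layout catalog from a YAML file.

    Format: a list of mappings with keys ``name``, ``k``, ``edge_changes``,
    ``vertex_lp_changes``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise LayoutError("layout config must be a list of layout entries")
    cat = LayoutCatalog()
    for entry in raw:
        cat.add(
            ITSLayout(
                name=str(entry["name"]),
                k=int(entry["k"]),
                edge_changes=tuple(int(c) for c in entry["edge_changes"]),
                vertex_lp_changes=tuple(int(d) for d in entry["vertex_lp_changes"]),
            )
        )
    return cat


def dump_catalog(catalog: LayoutCatalog, path) -> None:
    data = [
        {
            "name": lay.name,
            "k": lay.k,
            "edge_changes": list(lay.edge_changes),
            "vertex_lp_changes": list(lay.vertex_lp_changes),
        }
        for lay in catalog
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
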