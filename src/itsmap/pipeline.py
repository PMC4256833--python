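"""End-to-end atom mapping: cycle search followed by map extension."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem_graph import AtomMap, ReactionInstance, write_mapped_smiles
from .its_layouts import ITSLayout, LayoutCatalog, default_catalog
from .its_search import build_model, enumerate_candidates
from .map_extension import enumerate_atom_maps

logger = logging.getLogger("itsmap")

__all__ = ["RunConfig", "LayoutResult", "MappingResult", "run_mapping", "select_layouts"]


@dataclass
class RunConfig:
    """Configuration of one mapping run."""

    reaction: ReactionInstance
    k_values: tuple[int, ...] = (4, 6, 8)
    layouts: tuple[ITSLayout, ...] = ()
    mode: str = "basic"
    output: str = "all"  # first | all | count-only
    symmetry_breaking: bool = True
    degree_mode: str = "edges"

    def __post_init__(self):
        if not self.k_values:
            raise ValueError("k_values must be nonempty")
        if self.mode not in ("basic", "extended"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.output not in ("first", "all", "count-only"):
            raise ValueError(f"invalid output mode {self.output!r}")
        if not self.layouts:
            self.layouts = tuple(default_catalog())


@dataclass
class LayoutResult:
    layout: ITSLayout
    k: int
    n_candidates: int
    n_extendable: int | None = None
    atom_maps: list[AtomMap] = field(default_factory=list)


@dataclass
class MappingResult:
    reaction: ReactionInstance
    per_layout: list[LayoutResult] = field(default_factory=list)
    atom_maps: list[AtomMap] = field(default_factory=list)
    mapped_smiles: list[tuple[str, int, str]] = field(default_factory=list)
    minimal_k: int | None = None

    @property
    def n_candidates(self) -> int:
        return sum(r.n_candidates for r in self.per_layout)


def select_layouts(
    selection: str, catalog: LayoutCatalog | None = None
) -> tuple[ITSLayout, ...]:
    """Resolve a layout selection string (``homovalent``, ``all`` or names)."""
    cat = catalog or default_catalog()
    if selection == "all":
        return tuple(cat)
    if selection == "homovalent":
        return tuple(cat.homovalent())
    if selection == "ambivalent":
        return tuple(cat.ambivalent())
    return tuple(cat.get(name.strip()) for name in selection.split(","))


def run_mapping(config: RunConfig) -> MappingResult:
    """Search cycles for every selected layout/size, then extend to maps.

    Layouts are processed in ascending cycle size.  With ``output="first"``
    the run stops at the smallest k yielding a complete atom map; with
    ``"all"`` every candidate is extended and the maps are deduplicated at
    the reaction level; ``"count-only"`` skips extension.
    """
    result = MappingResult(reaction=config.reaction)
    chosen = sorted(
        (lay for lay in config.layouts if lay.k in config.k_values),
        key=lambda lay: (lay.k, lay.name),
    )
    seen_maps: set[tuple] = set()
    for layout in chosen:
        model = build_model(
            config.reaction,
            layout,
            mode=config.mode,
            symmetry_breaking=config.symmetry_breaking,
            degree_mode=config.degree_mode,
        )
        candidates = enumerate_candidates(model)
        lr = LayoutResult(layout=layout, k=layout.k, n_candidates=len(candidates))
        logger.info(
            "layout %s (k=%d, %s): %d candidate(s)",
            layout.name,
            layout.k,
            config.mode,
            len(candidates),
        )
        if config.output != "count-only":
            n_ext = 0
            for cand in candidates:
                maps = enumerate_atom_maps(config.reaction, cand)
                if maps:
                    n_ext += 1
                for amap in maps:
                    key = amap.as_pairs()
                    if key not in seen_maps:
                        seen_maps.add(key)
                        lr.atom_maps.append(amap)
                        result.atom_maps.append(amap)
                        result.mapped_smiles.append(
                            (
                                layout.name,
                                layout.k,
                                write_mapped_smiles(config.reaction, amap),
                            )
                        )
                if config.output == "first" and result.atom_maps:
                    break
            lr.n_extendable = n_ext
            logger.info(
                "layout %s (k=%d): %d extendable candidate(s), %d distinct map(s)",
                layout.name,
                layout.k,
                n_ext,
                len(lr.atom_maps),
            )
        result.per_layout.append(lr)
        if result.atom_maps and result.minimal_k is None:
            result.minimal_k = layout.k
        if config.output == "first" and result.atom_maps:
            break
    return result
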