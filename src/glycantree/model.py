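"""Domain model: Glycan = optional core tree + optional bag of unknown-linked subtrees.

The model separates *what is known to be connected* (the :class:`GlycanCore`,
a rooted tree of residues) from *what is present but unplaced* (the
:class:`GlycanBag`, whose items are rooted subtrees parsed from GlycoCT UND
sections).  A :class:`Residue` hosts one base, one substituent, or both (a
*composed* residue such as GlcNAc), plus a composition class label that
groups mass-isomeric building blocks (Hex, dHex, HexNAc, ...).

Child order inside a residue is stored as a sequence but carries no meaning:
branching is chemically unordered, and all comparisons (see
:func:`isomorphic`) treat children as multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

from glycantree.util import (
    UNDEFINED,
    UNKNOWN,
    Position,
    PositionSet,
    position_key,
    positions_sort_key,
)


@dataclass
class Base:
    """Monosaccharide skeleton of a residue.

    ``anomeric_carbon`` / ``parent_anomeric_carbon`` record the child-side /
    parent-side carbons of the glycosidic linkage to the parent residue
    (UNKNOWN at roots and for unresolved linkages).
    """

    name: str  # canonical basetype, e.g. "dglc-HEX", "dgro-dgal-NON"
    anomer: str = "x"  # a / b / x / o
    anomeric_carbon: Position = UNKNOWN
    parent_anomeric_carbon: Position = UNKNOWN
    ring: Tuple[Position, Position] = (UNKNOWN, UNKNOWN)
    modifications: frozenset = frozenset()

    def __post_init__(self):
        if self.anomer not in ("a", "b", "x", "o"):
            raise ValueError(f"invalid anomer {self.anomer!r}")

    @property
    def is_unknown(self) -> bool:
        """True when the skeleton itself is undetermined (x stem or SUG class)."""
        head, _, tail = self.name.rpartition("-")
        if tail == "SUG" or self.name == "SUG":
            return True
        return any(part.startswith("x") for part in head.split("-") if part)


@dataclass
class Substituent:
    """Non-sugar decoration; when composed, it lives inside the host residue."""

    name: str
    attach_position_on_base: Position = UNKNOWN  # only meaningful when composed
    child_position: Position = UNKNOWN


@dataclass
class Linkage:
    """Edge label of the residue tree (bond types + carbon position sets)."""

    parent_bond: str = "o"
    child_bond: str = "d"
    parent_positions: PositionSet = frozenset({UNKNOWN})
    child_positions: PositionSet = frozenset({UNKNOWN})

    def __post_init__(self):
        if not self.parent_positions or not self.child_positions:
            raise ValueError("linkage position sets must be non-empty")


@dataclass
class Residue:
    """A node of the core or of a bag-item tree."""

    id: int
    base: Optional[Base] = None
    substituent: Optional[Substituent] = None
    composition: str = UNDEFINED
    children: List[Tuple[Linkage, "Residue"]] = field(default_factory=list)
    is_root: bool = False

    def __post_init__(self):
        if self.base is None and self.substituent is None:
            raise ValueError("a residue needs a base, a substituent, or both")

    @property
    def is_composed(self) -> bool:
        return self.base is not None and self.substituent is not None

    def walk(self) -> Iterator["Residue"]:
        """Preorder traversal with deterministic child order."""
        yield self
        for _, child in sorted(self.children, key=_child_sort_key):
            yield from child.walk()


def _child_sort_key(item: Tuple[Linkage, Residue]):
    link, child = item
    return (
        positions_sort_key(link.parent_positions),
        child.composition,
        child.base.name if child.base else "",
        child.substituent.name if child.substituent else "",
        child.id,
    )


@dataclass
class GlycanCore:
    """The unambiguously connected part of a structure (a rooted tree)."""

    root: Residue

    def __post_init__(self):
        if not self.root.is_root:
            raise ValueError("core root must be marked is_root")


@dataclass
class GlycanBagItem:
    """One unknown-linked substructure: a rooted subtree plus attachment hints."""

    ordinal: int
    root: Residue
    parent_candidate_residue_ids: frozenset = frozenset()
    weights: Tuple[float, float] = (100.0, 100.0)

    def __post_init__(self):
        if not self.root.is_root:
            raise ValueError("bag item root must be marked is_root")


@dataclass
class GlycanBag:
    items: List[GlycanBagItem] = field(default_factory=list)

    def __post_init__(self):
        ordinals = [it.ordinal for it in self.items]
        if len(set(ordinals)) != len(ordinals):
            raise ValueError("bag item ordinals must be unique")


class Glycan:
    """One structure record: id + at most one core + at most one bag.

    The core/bag relationships are functional: the constructor is the only
    way to attach them and accepts at most one of each.  A record with
    neither core nor bag is an id-only structure (no structural encoding).
    """

    __slots__ = ("id", "_core", "_bag")

    def __init__(self, id: str, core: Optional[GlycanCore] = None, bag: Optional[GlycanBag] = None):
        if core is not None and not isinstance(core, GlycanCore):
            raise TypeError("core must be a GlycanCore")
        if bag is not None and not isinstance(bag, GlycanBag):
            raise TypeError("bag must be a GlycanBag")
        self.id = id
        self._core = core
        self._bag = bag

    @property
    def core(self) -> Optional[GlycanCore]:
        return self._core

    @property
    def bag(self) -> Optional[GlycanBag]:
        return self._bag

    def __repr__(self) -> str:
        n_core = len(list(self._core.root.walk())) if self._core else 0
        n_bag = len(self._bag.items) if self._bag else 0
        return f"Glycan({self.id!r}, core_residues={n_core}, bag_items={n_bag})"


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------


def residues(glycan: Glycan, scope: str = "both") -> List[Residue]:
    """All residues in deterministic order: core preorder, then bag items by ordinal.

    ``scope`` is ``core``, ``bag`` or ``both``; absent sections contribute
    nothing.
    """
    if scope not in ("core", "bag", "both"):
        raise ValueError(f"invalid scope {scope!r}")
    out: List[Residue] = []
    if scope in ("core", "both") and glycan.core is not None:
        out.extend(glycan.core.root.walk())
    if scope in ("bag", "both") and glycan.bag is not None:
        for item in sorted(glycan.bag.items, key=lambda it: it.ordinal):
            out.extend(item.root.walk())
    return out


def bag_item_count(glycan: Glycan) -> int:
    """Number of undefined sections (bag items); 0 when the bag is absent."""
    return len(glycan.bag.items) if glycan.bag is not None else 0


# -- isomorphism -------------------------------------------------------------


def _freeze_pos(p: Position):
    return "?" if p is UNKNOWN else p


def _freeze_posset(ps: PositionSet):
    return tuple(sorted((position_key(p), _freeze_pos(p)) for p in ps))


def _node_label(r: Residue):
    base = None
    if r.base is not None:
        b = r.base
        base = (
            b.name,
            b.anomer,
            _freeze_pos(b.anomeric_carbon),
            _freeze_pos(b.parent_anomeric_carbon),
            (_freeze_pos(b.ring[0]), _freeze_pos(b.ring[1])),
            tuple(sorted((str(_freeze_pos(p)), k) for p, k in b.modifications)),
        )
    sub = None
    if r.substituent is not None:
        s = r.substituent
        sub = (s.name, _freeze_pos(s.attach_position_on_base), _freeze_pos(s.child_position))
    return (base, sub, r.composition)


def _edge_label(l: Linkage):
    return (l.parent_bond, l.child_bond, _freeze_posset(l.parent_positions), _freeze_posset(l.child_positions))


def canonical_form(root: Residue):
    """Order-independent canonical tuple of a residue subtree (ids ignored)."""
    children = sorted(
        ((_edge_label(link), canonical_form(child)) for link, child in root.children),
        key=repr,  # total order over the heterogeneous label tuples
    )
    return (_node_label(root), tuple(children))


def isomorphic(a: Glycan, b: Glycan) -> bool:
    """Label-preserving rooted-tree isomorphism with unordered children.

    Cores must be isomorphic (or both absent); bags must contain pairwise
    isomorphic items *as multisets* (ordinals and attachment-candidate ids,
    which depend on numbering, are ignored; statistical weights compare).
    Glycan ids are ignored.
    """
    ca = canonical_form(a.core.root) if a.core else None
    cb = canonical_form(b.core.root) if b.core else None
    if ca != cb:
        return False
    ia = sorted(
        ((canonical_form(it.root), it.weights) for it in (a.bag.items if a.bag else [])),
        key=repr,
    )
    ib = sorted(
        ((canonical_form(it.root), it.weights) for it in (b.bag.items if b.bag else [])),
        key=repr,
    )
    return ia == ib
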