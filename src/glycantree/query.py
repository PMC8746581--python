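"""Precise and ambiguous substructure search over built Glycans.

Patterns are written in a compact bracketed notation modelled on condensed
IUPAC: ``Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc``.  The rightmost residue is
the pattern root (the reducing end); an optional
``(<anomer><child>-<parent>)`` annotation constrains the linkage to the
parent and the residue's anomer; ``?`` is a wildcard (as a token: any
residue; as an anomer or position: unconstrained).  A ``[...]`` branch with
a linkage annotation binds IUPAC-style to the residue at its right; an
annotation-free branch decorates the residue written at its left, so
``Gal[Fuc]GlcNAc[Fuc]`` is a fucosylated Gal on a fucosylated GlcNAc root.
Omitting annotations, as in ``Gal[Fuc]GlcNAc[Fuc]``, leaves all edges
unconstrained — the fuzzy form of that pattern retrieves every Lewis
A/B/X/Y-carrying structure even when the data's linkages are unknown.

Matching semantics
------------------
* ``anchor``: *anywhere* (pattern root maps to any residue), *root*
  (pattern root maps to a tree root — the core root or a bag-item root),
  *whole* (the mapping is a bijection onto an entire core or bag-item tree).
* ``mode``: in *strict* mode an UNKNOWN data value fails any named
  constraint; in *fuzzy* mode UNKNOWN data satisfies everything and
  position sets match on non-empty intersection.  In both modes a *named*
  data value never satisfies a *different* named constraint (fuzziness is
  about missing knowledge, not about collapsing Gal/Glc).
* ``scope``: *core*, *bag* or *both*; one pattern never spans the
  core→bag boundary (bag items are, by definition, not connected to the
  core).
* Children match injectively and unordered; alternative data positions
  ("3|6") match a single query position by membership.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from glycantree.errors import (
    TooLarge,
    UnbalancedBracket,
    UnknownQueryId,
    UnknownToken,
)
from glycantree.model import (
    Glycan,
    GlycanBag,
    GlycanBagItem,
    Linkage,
    Residue,
    bag_item_count,
    residues,
)
from glycantree.rules import RuleSet, default_rules
from glycantree.util import UNDEFINED, UNKNOWN, PositionSet

ANY = "ANY"
BASETYPE = "BASETYPE"
COMPOSITION = "COMPOSITION"


# ---------------------------------------------------------------------------
# Pattern types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeConstraint:
    """Constraint on one residue.

    ``level``/``name`` constrain the skeleton (exact basetype string, a
    composition class, or anything); the substituent constraint is
    ``("required", name)``, ``("forbidden", None)`` or ``("any", None)``;
    ``base_presence`` lets substituent-only tokens (phosphate, sulfate)
    exclude residues that carry a base.
    """

    level: str = ANY
    name: Optional[str] = None
    substituent: Tuple[str, Optional[str]] = ("any", None)
    anomer: str = "any"  # "a" | "b" | "any"
    base_presence: str = "any"  # "required" | "forbidden" | "any"

    def __post_init__(self):
        if (self.name is None) != (self.level == ANY):
            raise ValueError("name must be present iff level is not ANY")


@dataclass(frozen=True)
class EdgeConstraint:
    """Constraint on the linkage between a pattern node and its parent."""

    parent_positions: Optional[PositionSet] = None  # None = ANY
    child_positions: Optional[PositionSet] = None

    def __post_init__(self):
        for ps in (self.parent_positions, self.child_positions):
            if ps is not None and not ps:
                raise ValueError("position constraint sets must be non-empty")


@dataclass
class PatternNode:
    id: int
    constraint: NodeConstraint
    children: List[Tuple[EdgeConstraint, "PatternNode"]] = field(default_factory=list)

    def walk(self):
        yield self
        for _, c in self.children:
            yield from c.walk()


@dataclass
class QueryPattern:
    root: PatternNode
    anchor: str = "anywhere"  # anywhere | root | whole
    ambiguity: str = "fuzzy"  # strict | fuzzy
    scope: str = "both"  # core | bag | both

    def __post_init__(self):
        if self.anchor not in ("anywhere", "root", "whole"):
            raise ValueError(f"invalid anchor {self.anchor!r}")
        if self.ambiguity not in ("strict", "fuzzy"):
            raise ValueError(f"invalid ambiguity {self.ambiguity!r}")
        if self.scope not in ("core", "bag", "both"):
            raise ValueError(f"invalid scope {self.scope!r}")

    @property
    def size(self) -> int:
        return sum(1 for _ in self.root.walk())

    def with_options(self, **kw) -> "QueryPattern":
        return QueryPattern(self.root, **{**dict(anchor=self.anchor, ambiguity=self.ambiguity, scope=self.scope), **kw})


@dataclass(frozen=True)
class MatchResult:
    glycan_id: str
    location: Tuple[str, int]  # ("core", 0) or ("bag", ordinal)
    mapping: Tuple[Tuple[int, int], ...]  # sorted (pattern_node_id, residue_id)

    def mapping_dict(self) -> Dict[int, int]:
        return dict(self.mapping)


# ---------------------------------------------------------------------------
# Token resolution
# ---------------------------------------------------------------------------

# common residue names → constraints.  Fuc is matched at composition level
# (dHex) because its basetype string lgal-HEX alone cannot be told apart
# from L-galactose without the 6:d modification.
_NAME_TABLE: Dict[str, NodeConstraint] = {
    "Glc": NodeConstraint(BASETYPE, "dglc-HEX", ("forbidden", None)),
    "Gal": NodeConstraint(BASETYPE, "dgal-HEX", ("forbidden", None)),
    "Man": NodeConstraint(BASETYPE, "dman-HEX", ("forbidden", None)),
    "GlcNAc": NodeConstraint(BASETYPE, "dglc-HEX", ("required", "n-acetyl")),
    "GalNAc": NodeConstraint(BASETYPE, "dgal-HEX", ("required", "n-acetyl")),
    "ManNAc": NodeConstraint(BASETYPE, "dman-HEX", ("required", "n-acetyl")),
    "GlcN": NodeConstraint(BASETYPE, "dglc-HEX", ("required", "amino")),
    "Neu5Ac": NodeConstraint(BASETYPE, "dgro-dgal-NON", ("required", "n-acetyl")),
    "Neu5Gc": NodeConstraint(BASETYPE, "dgro-dgal-NON", ("required", "n-glycolyl")),
    "Kdn": NodeConstraint(BASETYPE, "dgro-dgal-NON", ("forbidden", None)),
    "Fuc": NodeConstraint(COMPOSITION, "dHex", ("forbidden", None)),
    "Xyl": NodeConstraint(BASETYPE, "dxyl-PEN", ("forbidden", None)),
}

_SUBSTITUENT_TOKENS = {
    "phosphate": "phosphate",
    "sulfate": "sulfate",
    "P": "phosphate",
    "S": "sulfate",
}


def _resolve_token(token: str, rules: RuleSet) -> NodeConstraint:
    if token == "?":
        return NodeConstraint()
    if token in _NAME_TABLE:
        return _NAME_TABLE[token]
    if token in _SUBSTITUENT_TOKENS:
        return NodeConstraint(
            substituent=("required", _SUBSTITUENT_TOKENS[token]), base_presence="forbidden"
        )
    # composition class labels known to the rule set (Hex, dHex, HexNAc ...)
    classes = {r.composition_class for r in rules.composition_rules}
    classes |= {r.composition_class for r in rules.composed_rules}
    if token in classes:
        return NodeConstraint(COMPOSITION, token)
    raise UnknownToken(f"unknown residue token {token!r}")


# ---------------------------------------------------------------------------
# Pattern compiler
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(?P<open>\[)|(?P<close>\])"
    r"|(?P<name>[A-Za-z][A-Za-z0-9]*|\?)"
    r"(?:\((?P<anomer>[ab?])?(?P<child>\?|\d+)-(?P<parent>\?|-1|\d+(?:\|\d+)*)\))?"
)


def compile_pattern(
    spec: str,
    rules: Optional[RuleSet] = None,
    anchor: str = "anywhere",
    ambiguity: str = "fuzzy",
    scope: str = "both",
) -> QueryPattern:
    """Compile the bracketed notation into a :class:`QueryPattern`."""
    rules = rules or default_rules()
    pos = 0
    spec = spec.strip()
    # stack of pending sibling lists; entries are (edge, node, bracketed)
    items: List[List] = [[]]
    counter = [0]

    def new_node(token: str, m) -> Tuple[EdgeConstraint, PatternNode]:
        constraint = _resolve_token(token, rules)
        anomer = m.group("anomer")
        if anomer in ("a", "b"):
            constraint = replace(constraint, anomer=anomer)
        child_ps = parent_ps = None
        if m.group("child") and m.group("child") != "?":
            child_ps = frozenset({int(m.group("child"))})
        ptok = m.group("parent")
        if ptok and ptok not in ("?", "-1"):
            parent_ps = frozenset(int(t) for t in ptok.split("|"))
        counter[0] += 1
        node = PatternNode(counter[0], constraint)
        return EdgeConstraint(parent_ps, child_ps), node

    while pos < len(spec):
        if spec[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(spec, pos)
        if not m or m.end() == pos:
            raise UnknownToken(f"cannot tokenize pattern at {spec[pos:]!r}")
        pos = m.end()
        if m.group("open"):
            items.append([])
        elif m.group("close"):
            if len(items) < 2:
                raise UnbalancedBracket(f"stray ']' in {spec!r}")
            group = items.pop()
            if len(group) != 1:
                raise UnbalancedBracket("a branch must contain exactly one rooted sequence")
            edge, node, _ = group[0]
            annotated = edge.parent_positions is not None or edge.child_positions is not None
            chain = [e for e in items[-1] if not e[2]]
            if not annotated and chain:
                # an annotation-free branch ("Gal[Fuc]...") decorates the
                # residue written at its left; an annotated one binds
                # IUPAC-style to the residue at its right
                chain[-1][1].children.append((edge, node))
            else:
                items[-1].append((edge, node, True))
        else:
            edge, node = new_node(m.group("name"), m)
            # the new residue receives everything accumulated to its left
            node.children = [(e, n) for e, n, _ in items[-1]]
            items[-1] = [(edge, node, False)]
    if len(items) != 1:
        raise UnbalancedBracket(f"unclosed '[' in {spec!r}")
    # trailing bracket groups (as in "Gal[Fuc]GlcNAc[Fuc]") bind back to the
    # residue on their left, i.e. the pattern root
    entries = items[0]
    if not entries or entries[0][2]:
        raise UnknownToken(f"pattern {spec!r} does not reduce to a single root")
    _, root, _ = entries[0]
    for edge, node, bracketed in entries[1:]:
        if not bracketed:
            raise UnknownToken(f"pattern {spec!r} does not reduce to a single root")
        root.children.append((edge, node))
    # renumber ids in preorder for stable reports
    for i, node in enumerate(root.walk(), start=1):
        node.id = i
    return QueryPattern(root, anchor=anchor, ambiguity=ambiguity, scope=scope)


_PATTERN_LIB: Optional[Dict[str, dict]] = None


def pattern_library() -> Dict[str, dict]:
    """Shipped pattern notation library (Lewis antigens, N-core, O-cores...)."""
    global _PATTERN_LIB
    if _PATTERN_LIB is None:
        text = resources.files("glycantree").joinpath("data/patterns.json").read_text()
        _PATTERN_LIB = {e["id"]: e for e in json.loads(text)}
    return _PATTERN_LIB


def library_pattern(pattern_id: str, rules: Optional[RuleSet] = None, **options) -> QueryPattern:
    lib = pattern_library()
    if pattern_id not in lib:
        raise UnknownToken(f"unknown pattern id {pattern_id!r}")
    entry = lib[pattern_id]
    opts = {"anchor": entry.get("anchor", "anywhere")}
    opts.update(options)
    return compile_pattern(entry["pattern"], rules, **opts)


# ---------------------------------------------------------------------------
# Constraint satisfaction (shared by the matcher and the brute-force oracle)
# ---------------------------------------------------------------------------


def _node_ok(c: NodeConstraint, r: Residue, fuzzy: bool) -> bool:
    if c.base_presence == "required" and r.base is None:
        return False
    if c.base_presence == "forbidden" and r.base is not None:
        return False
    if c.level == BASETYPE:
        if r.base is None:
            return False
        if r.base.name != c.name and not (fuzzy and r.base.is_unknown):
            return False
    elif c.level == COMPOSITION:
        if r.composition != c.name and not (fuzzy and r.composition == UNDEFINED):
            return False
    kind, name = c.substituent
    if kind == "required":
        if r.substituent is None or r.substituent.name != name:
            return False
    elif kind == "forbidden":
        if r.substituent is not None:
            return False
    if c.anomer in ("a", "b"):
        if r.base is None:
            return False
        if r.base.anomer != c.anomer and not (fuzzy and r.base.anomer == "x"):
            return False
    return True


def _positions_ok(query: Optional[PositionSet], data: PositionSet, fuzzy: bool) -> bool:
    if query is None:
        return True
    if data == frozenset({UNKNOWN}):
        return fuzzy
    if fuzzy:
        return bool(query & data)
    if len(query) == 1:
        (p,) = query
        return p in data
    return query == data


def _edge_ok(c: EdgeConstraint, l: Linkage, fuzzy: bool) -> bool:
    return _positions_ok(c.parent_positions, l.parent_positions, fuzzy) and _positions_ok(
        c.child_positions, l.child_positions, fuzzy
    )


# ---------------------------------------------------------------------------
# Matcher
# ---------------------------------------------------------------------------


def _trees_in_scope(glycan: Glycan, scope: str) -> List[Tuple[Tuple[str, int], Residue]]:
    trees = []
    if scope in ("core", "both") and glycan.core is not None:
        trees.append((("core", 0), glycan.core.root))
    if scope in ("bag", "both") and glycan.bag is not None:
        for item in sorted(glycan.bag.items, key=lambda it: it.ordinal):
            trees.append((("bag", item.ordinal), item.root))
    return trees


def _match_at(
    pnode: PatternNode, residue: Residue, fuzzy: bool, whole: bool
) -> List[Dict[int, int]]:
    """All mappings of the pattern subtree rooted at pnode onto the data
    subtree rooted at residue (residue is the image of pnode)."""
    if not _node_ok(pnode.constraint, residue, fuzzy):
        return []
    pchildren = pnode.children
    dchildren = residue.children
    if whole and len(pchildren) != len(dchildren):
        return []
    if not pchildren:
        return [{pnode.id: residue.id}]

    # injective assignment of pattern children to distinct data children
    results: List[Dict[int, int]] = []
    seen = set()

    def assign(i: int, used: frozenset, acc: Dict[int, int]):
        if i == len(pchildren):
            key = tuple(sorted(acc.items()))
            if key not in seen:
                seen.add(key)
                results.append(dict(acc))
            return
        edge_c, pchild = pchildren[i]
        for j, (link, dchild) in enumerate(dchildren):
            if j in used:
                continue
            if not _edge_ok(edge_c, link, fuzzy):
                continue
            for sub in _match_at(pchild, dchild, fuzzy, whole):
                assign(i + 1, used | {j}, {**acc, **sub})

    assign(0, frozenset(), {pnode.id: residue.id})
    return results


def match(pattern: QueryPattern, glycan: Glycan) -> List[MatchResult]:
    """All matches of a pattern in one glycan, deterministically ordered."""
    fuzzy = pattern.ambiguity == "fuzzy"
    out: List[MatchResult] = []
    for location, tree_root in _trees_in_scope(glycan, pattern.scope):
        if pattern.anchor == "anywhere":
            candidates = list(tree_root.walk())
        else:
            candidates = [tree_root]
        whole = pattern.anchor == "whole"
        for residue in candidates:
            for mapping in _match_at(pattern.root, residue, fuzzy, whole):
                out.append(
                    MatchResult(glycan.id, location, tuple(sorted(mapping.items())))
                )
    out.sort(key=lambda m: (m.glycan_id, m.location, m.mapping))
    # deduplicate identical mappings found through different branches
    deduped = []
    for m in out:
        if not deduped or deduped[-1] != m:
            deduped.append(m)
    return deduped


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_match(pattern: QueryPattern, glycan: Glycan, guard: int = 12) -> List[MatchResult]:
    """Exhaustive-enumeration matcher (testing oracle).

    Enumerates every injective mapping of pattern nodes onto residues of a
    single tree, keeping those that honor parent/child adjacency, node and
    edge constraints, and the anchor option.  Guarded to ≤ ``guard`` total
    residues.
    """
    from itertools import permutations

    total = len(residues(glycan, "both"))
    if total > guard:
        raise TooLarge(f"glycan has {total} residues; brute force is guarded at {guard}")
    fuzzy = pattern.ambiguity == "fuzzy"
    pnodes = list(pattern.root.walk())
    # pattern adjacency: (parent id, edge, child id); parent of root: None
    pedges = []
    for pn in pnodes:
        for edge_c, child in pn.children:
            pedges.append((pn.id, edge_c, child.id))

    out: List[MatchResult] = []
    for location, tree_root in _trees_in_scope(glycan, pattern.scope):
        dnodes = list(tree_root.walk())
        by_id = {r.id: r for r in dnodes}
        # data adjacency: child residue id -> (parent residue id, linkage)
        dparent: Dict[int, Tuple[int, Linkage]] = {}
        for r in dnodes:
            for link, c in r.children:
                dparent[c.id] = (r.id, link)
        for images in permutations(dnodes, len(pnodes)):
            mapping = {pn.id: img.id for pn, img in zip(pnodes, images)}
            if not all(
                _node_ok(pn.constraint, by_id[mapping[pn.id]], fuzzy) for pn in pnodes
            ):
                continue
            ok = True
            for parent_id, edge_c, child_id in pedges:
                got = dparent.get(mapping[child_id])
                if got is None or got[0] != mapping[parent_id]:
                    ok = False
                    break
                if not _edge_ok(edge_c, got[1], fuzzy):
                    ok = False
                    break
            if not ok:
                continue
            if pattern.anchor in ("root", "whole") and mapping[pattern.root.id] != tree_root.id:
                continue
            if pattern.anchor == "whole" and len(pnodes) != len(dnodes):
                continue
            out.append(MatchResult(glycan.id, location, tuple(sorted(mapping.items()))))
    out.sort(key=lambda m: (m.glycan_id, m.location, m.mapping))
    deduped = []
    for m in out:
        if not deduped or deduped[-1] != m:
            deduped.append(m)
    return deduped


# ---------------------------------------------------------------------------
# Bag multiset search and chain search
# ---------------------------------------------------------------------------


def match_bag_multiset(item_patterns: Sequence[QueryPattern], glycan: Glycan) -> bool:
    """True iff the patterns match within *distinct* bag items (injectively).

    This is the bag-only use case: e.g. [Fuc, GlcNAc] asks for a bag holding
    at least one free fucose item and at least one free GlcNAc item.
    """
    if glycan.bag is None:
        return not item_patterns
    items = sorted(glycan.bag.items, key=lambda it: it.ordinal)

    def hits(pattern: QueryPattern, item: GlycanBagItem) -> bool:
        # match within this single item: wrap it as a one-item bag
        probe = Glycan(glycan.id, None, GlycanBag([item]))
        return bool(match(pattern.with_options(scope="bag"), probe))

    table = [[hits(p, it) for it in items] for p in item_patterns]

    def assign(i: int, used: frozenset) -> bool:
        if i == len(item_patterns):
            return True
        return any(
            table[i][j] and assign(i + 1, used | {j})
            for j in range(len(items))
            if j not in used
        )

    return assign(0, frozenset())


def chain_search(
    constraint: NodeConstraint, min_length: int, glycan: Glycan, scope: str = "both"
) -> List[MatchResult]:
    """Maximal parent→child chains of ≥ ``min_length`` residues all satisfying
    ``constraint`` (strict node semantics on names, fuzzy on nothing — the
    constraint is typically a composition class, e.g. two consecutively
    linked sialic acids)."""
    if min_length < 1:
        raise ValueError("min_length must be ≥ 1")

    def sat(r: Residue) -> bool:
        return _node_ok(constraint, r, fuzzy=False)

    def chains_from(r: Residue) -> List[List[int]]:
        # all maximal downward chains of satisfying residues starting at r
        tails = [
            chain for _, child in r.children if sat(child) for chain in chains_from(child)
        ]
        return [[r.id] + t for t in tails] if tails else [[r.id]]

    out: List[MatchResult] = []
    for location, tree_root in _trees_in_scope(glycan, scope):
        starts = []

        def collect(r: Residue, parent_sat: bool):
            if sat(r) and not parent_sat:
                starts.append(r)
            for _, child in r.children:
                collect(child, sat(r))

        collect(tree_root, False)
        for start in starts:
            for chain in chains_from(start):
                if len(chain) >= min_length:
                    out.append(
                        MatchResult(
                            glycan.id,
                            location,
                            tuple((i + 1, rid) for i, rid in enumerate(chain)),
                        )
                    )
    out.sort(key=lambda m: (m.glycan_id, m.location, m.mapping))
    return out


# ---------------------------------------------------------------------------
# Query catalogs
# ---------------------------------------------------------------------------


def _has_residue_root(g: Glycan) -> bool:
    return g.core is not None or bag_item_count(g) > 0


def run_catalog_query(
    query_id, corpus: Sequence[Glycan], rules: Optional[RuleSet] = None, structure_id=None
):
    """Run one query of the validation catalogs over a corpus of built Glycans.

    Numeric ids 1..16 are the quantitative catalog (counts and count
    vectors); Q1..Q6 are the qualitative catalog (id lists / listings).
    """
    rules = rules or default_rules()
    qid = str(query_id)

    if qid == "1":
        # structures whose core root holds only a substituent
        return sum(
            1
            for g in corpus
            if g.core is not None
            and g.core.root.base is None
            and g.core.root.substituent is not None
        )
    if qid in ("2", "16"):
        return sum(1 for g in corpus if _has_residue_root(g))
    if qid == "3":
        names = set()
        for g in corpus:
            roots = []
            if g.core is not None:
                roots.append(g.core.root)
            if g.bag is not None:
                roots.extend(it.root for it in g.bag.items)
            names.update(r.base.name for r in roots if r.base is not None)
        return len(names)
    if qid == "4":
        return len(
            {r.base.name for g in corpus for r in residues(g, "both") if r.base is not None}
        )
    if qid == "5":
        return len(
            {
                r.substituent.name
                for g in corpus
                for r in residues(g, "both")
                if r.substituent is not None
            }
        )
    if qid == "6":
        return len(
            {
                r.substituent.name
                for g in corpus
                for r in residues(g, "both")
                if r.substituent is not None and r.base is None
            }
        )
    if qid == "7":
        pat = library_pattern("di_sialyl_tn", rules, ambiguity="strict")
        return sum(1 for g in corpus if match(pat, g))
    if qid in ("8", "9", "10"):
        def root_is(g: Glycan, pred) -> bool:
            return g.core is not None and pred(g.core.root)

        if qid == "8":  # starts with fucose (the only dHex member shipped)
            pred = lambda r: r.composition == "dHex" and r.substituent is None
        elif qid == "9":  # starts with mannose
            pred = lambda r: r.base is not None and r.base.name == "dman-HEX" and r.substituent is None
        else:  # starts with xylose
            pred = lambda r: r.base is not None and r.base.name == "dxyl-PEN" and r.substituent is None
        return sum(1 for g in corpus if root_is(g, pred))
    if qid == "11":
        return [sum(1 for g in corpus if bag_item_count(g) >= k) for k in range(1, 10)]
    if qid == "12":
        return [sum(1 for g in corpus if bag_item_count(g) == k) for k in range(1, 10)]
    if qid == "13":
        return sum(1 for g in corpus if g.core is None)
    if qid == "14":
        return len(corpus)
    if qid == "15":
        return sum(1 for g in corpus if g.core is not None)
    if qid == "Q1":
        pat = library_pattern("n_core", rules, anchor="whole", ambiguity="strict", scope="core")
        return sorted(g.id for g in corpus if match(pat, g))
    if qid == "Q2":
        out = []
        for g in corpus:
            rs = residues(g, "both")
            if not rs:
                continue
            def is_glcnac(r: Residue) -> bool:
                return (
                    r.base is not None
                    and r.base.name == "dglc-HEX"
                    and r.substituent is not None
                    and r.substituent.name == "n-acetyl"
                )
            def is_phosphate(r: Residue) -> bool:
                return r.base is None and r.substituent is not None and r.substituent.name == "phosphate"
            if (
                all(is_glcnac(r) or is_phosphate(r) for r in rs)
                and any(is_glcnac(r) for r in rs)
                and any(is_phosphate(r) for r in rs)
            ):
                out.append(g.id)
        return sorted(out)
    if qid == "Q3":
        if structure_id is None:
            raise UnknownQueryId("Q3 needs a structure_id")
        for g in corpus:
            if g.id == str(structure_id) or g.id == structure_id:
                return [it.ordinal for it in (g.bag.items if g.bag else [])]
        return []
    if qid in ("Q4", "Q5"):
        sial = NodeConstraint(COMPOSITION, "Neu5Ac")
        ids = [g.id for g in corpus if chain_search(sial, 2, g)]
        if qid == "Q5":
            core1 = library_pattern("o_core1", rules, anchor="root", ambiguity="strict", scope="core")
            ids = [
                g.id for g in corpus if g.id in set(ids) and match(core1, g)
            ]
        return sorted(ids)
    if qid == "Q6":
        return sorted(
            g.id
            for g in corpus
            if g.core is not None and not g.core.root.children
        )
    raise UnknownQueryId(f"unknown query id {query_id!r}")
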