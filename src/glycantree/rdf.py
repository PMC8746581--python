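"""RDF export of built Glycans as individuals of the tree+bag vocabulary.

Every structure becomes a set of typed individuals under a caller-supplied
base URI: the Glycan, at most one GlycanCore and one GlycanBag (the
relationships are functional), Residue nodes (roots additionally typed
ResidueRoot), Base/Substituent individuals carrying name/anomer/position
literals, composition literals on residues, direct child links between
residues, and GlycanBagItem individuals inside the bag.

The class/property vocabulary lives in a fixed documented namespace
(:data:`VOCAB`); individuals live under the base URI, with path segments
derived from the model's deterministic residue ids, so identical input
yields byte-identical sorted N-Triples.

Ancestor/descendant closure predicates are *not* materialized by default —
only direct child links — because closures are derivable and bloat the
store; ``materialize_closures=True`` opts in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple
from urllib.parse import urlparse

from rdflib import Graph, Literal, Namespace, RDF, URIRef

from glycantree.errors import InvalidBaseURI
from glycantree.glycoct import _fmt_ring  # ring bound formatting ("x" for unknown)
from glycantree.model import (
    Base,
    Glycan,
    GlycanBag,
    GlycanBagItem,
    GlycanCore,
    Linkage,
    Residue,
    Substituent,
    bag_item_count,
    residues,
)
from glycantree.util import (
    UNKNOWN,
    format_position,
    format_positions,
    parse_position,
    parse_positions,
)

#: Documented placeholder namespace for the model vocabulary.
VOCAB = Namespace("https://glycantree.example.org/model#")


@dataclass
class TripleDoc:
    """An exported RDF document: a set of triples plus its base URI."""

    triples: frozenset
    base_uri: str

    @property
    def graph(self) -> Graph:
        g = Graph()
        g.bind("gt", VOCAB)
        for t in self.triples:
            g.add(t)
        return g

    def to_ntriples(self) -> str:
        """Sorted N-Triples (byte-stable for identical input)."""
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in self.triples
        )
        return "\n".join(lines) + "\n"

    def to_turtle(self) -> str:
        return self.graph.serialize(format="turtle")

    def predicate_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for _, p, _ in self.triples:
            name = str(p).rsplit("#", 1)[-1]
            counts[name] = counts.get(name, 0) + 1
        return counts

    def type_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for _, p, o in self.triples:
            if p == RDF.type:
                name = str(o).rsplit("#", 1)[-1]
                counts[name] = counts.get(name, 0) + 1
        return counts


def _check_base_uri(base_uri: str) -> str:
    parsed = urlparse(base_uri)
    if not parsed.scheme or not parsed.netloc:
        raise InvalidBaseURI(f"base URI must be absolute: {base_uri!r}")
    return base_uri if base_uri.endswith(("/", "#")) else base_uri + "/"


def export_glycan(glycan: Glycan, base_uri: str, materialize_closures: bool = False) -> TripleDoc:
    """Serialize one built Glycan as RDF individuals."""
    base = _check_base_uri(base_uri)
    triples: List[Tuple] = []
    gid = str(glycan.id) if glycan.id else "unnamed"
    g_uri = URIRef(f"{base}glycan/{gid}")
    triples.append((g_uri, RDF.type, VOCAB.Glycan))

    def residue_uri(r: Residue) -> URIRef:
        return URIRef(f"{base}glycan/{gid}/residue/{r.id}")

    def emit_residue(r: Residue, is_root: bool) -> None:
        r_uri = residue_uri(r)
        triples.append((r_uri, RDF.type, VOCAB.Residue))
        if is_root:
            triples.append((r_uri, RDF.type, VOCAB.ResidueRoot))
        triples.append((r_uri, VOCAB.composition, Literal(r.composition)))
        if r.base is not None:
            b_uri = URIRef(f"{base}glycan/{gid}/residue/{r.id}/base")
            b = r.base
            triples.extend(
                [
                    (r_uri, VOCAB.hasBase, b_uri),
                    (b_uri, RDF.type, VOCAB.Base),
                    (b_uri, VOCAB.name, Literal(b.name)),
                    (b_uri, VOCAB.anomer, Literal(b.anomer)),
                    (b_uri, VOCAB.anomericCarbon, Literal(format_position(b.anomeric_carbon))),
                    (
                        b_uri,
                        VOCAB.parentAnomericCarbon,
                        Literal(format_position(b.parent_anomeric_carbon)),
                    ),
                    (b_uri, VOCAB.ring, Literal(f"{_fmt_ring(b.ring[0])}:{_fmt_ring(b.ring[1])}")),
                ]
            )
            for pos, kind in sorted(b.modifications, key=lambda m: (str(m[0]), m[1])):
                triples.append(
                    (b_uri, VOCAB.modification, Literal(f"{format_position(pos)}:{kind}"))
                )
        if r.substituent is not None:
            s_uri = URIRef(f"{base}glycan/{gid}/residue/{r.id}/substituent")
            s = r.substituent
            triples.extend(
                [
                    (r_uri, VOCAB.hasSubstituent, s_uri),
                    (s_uri, RDF.type, VOCAB.Substituent),
                    (s_uri, VOCAB.name, Literal(s.name)),
                    (s_uri, VOCAB.attachPosition, Literal(format_position(s.attach_position_on_base))),
                    (s_uri, VOCAB.childPosition, Literal(format_position(s.child_position))),
                ]
            )
        for link, child in r.children:
            c_uri = residue_uri(child)
            triples.append((r_uri, VOCAB.hasChildResidue, c_uri))
            # each non-root residue has exactly one inbound linkage, so the
            # edge label is stored on the child
            triples.extend(
                [
                    (c_uri, VOCAB.linkageParentBond, Literal(link.parent_bond)),
                    (c_uri, VOCAB.linkageChildBond, Literal(link.child_bond)),
                    (c_uri, VOCAB.linkageParentPositions, Literal(format_positions(link.parent_positions))),
                    (c_uri, VOCAB.linkageChildPositions, Literal(format_positions(link.child_positions))),
                ]
            )
            emit_residue(child, is_root=False)

    if glycan.core is not None:
        core_uri = URIRef(f"{base}glycan/{gid}/core")
        triples.append((g_uri, VOCAB.hasGlycanCore, core_uri))
        triples.append((core_uri, RDF.type, VOCAB.GlycanCore))
        triples.append((core_uri, VOCAB.hasRootResidue, residue_uri(glycan.core.root)))
        emit_residue(glycan.core.root, is_root=True)

    if glycan.bag is not None:
        bag_uri = URIRef(f"{base}glycan/{gid}/bag")
        triples.append((g_uri, VOCAB.hasGlycanBag, bag_uri))
        triples.append((bag_uri, RDF.type, VOCAB.GlycanBag))
        for item in sorted(glycan.bag.items, key=lambda it: it.ordinal):
            it_uri = URIRef(f"{base}glycan/{gid}/bag/{item.ordinal}")
            triples.extend(
                [
                    (bag_uri, VOCAB.hasItem, it_uri),
                    (it_uri, RDF.type, VOCAB.GlycanBagItem),
                    (it_uri, VOCAB.ordinal, Literal(item.ordinal)),
                    (it_uri, VOCAB.majorWeight, Literal(item.weights[0])),
                    (it_uri, VOCAB.minorWeight, Literal(item.weights[1])),
                    (it_uri, VOCAB.hasRootResidue, residue_uri(item.root)),
                ]
            )
            for cand in sorted(item.parent_candidate_residue_ids):
                triples.append((it_uri, VOCAB.parentCandidate, Literal(cand)))
            emit_residue(item.root, is_root=True)

    if materialize_closures:
        # derive ancestor/descendant closure links from the direct child links
        children: Dict[URIRef, List[URIRef]] = {}
        for s, p, o in triples:
            if p == VOCAB.hasChildResidue:
                children.setdefault(s, []).append(o)

        def descendants(u: URIRef):
            for c in children.get(u, []):
                yield c
                yield from descendants(c)

        for u in list(children):
            for d in descendants(u):
                triples.append((u, VOCAB.hasDescendantResidue, d))
                triples.append((d, VOCAB.hasAncestorResidue, u))

    return TripleDoc(frozenset(triples), base)


def triple_census(glycan: Glycan) -> Dict[str, int]:
    """Closed-form per-predicate census an export must reproduce."""
    core_rs = residues(glycan, "core")
    bag_rs = residues(glycan, "bag")
    all_rs = core_rs + bag_rs
    n_items = bag_item_count(glycan)
    child_links = (len(core_rs) - 1 if glycan.core is not None else 0) + sum(
        len(list(it.root.walk())) - 1 for it in (glycan.bag.items if glycan.bag else [])
    )
    return {
        "hasBase": sum(1 for r in all_rs if r.base is not None),
        "hasSubstituent": sum(1 for r in all_rs if r.substituent is not None),
        "hasChildResidue": child_links,
        "GlycanBagItem": n_items,
        "hasGlycanCore": 1 if glycan.core is not None else 0,
        "hasGlycanBag": 1 if glycan.bag is not None else 0,
    }


# ---------------------------------------------------------------------------
# Reader (round-trip support)
# ---------------------------------------------------------------------------


def import_glycan(doc: TripleDoc) -> Glycan:
    """Reconstruct a Glycan from an exported document (inverse of export).

    Ids are re-derived from the residue URIs; the result is isomorphic to
    the exported input.
    """
    g = doc.graph
    glycan_uri = next(g.subjects(RDF.type, VOCAB.Glycan))
    gid = str(glycan_uri).rsplit("/", 1)[-1]

    def lit(s, p, default=None):
        v = g.value(s, p)
        return str(v) if v is not None else default

    def read_residue(r_uri, is_root: bool) -> Residue:
        rid = int(str(r_uri).rsplit("/", 1)[-1])
        base = None
        b_uri = g.value(r_uri, VOCAB.hasBase)
        if b_uri is not None:
            ring_tok = lit(b_uri, VOCAB.ring, "x:x").split(":")
            mods = frozenset(
                (parse_position(str(m).split(":")[0]), str(m).split(":")[1])
                for m in g.objects(b_uri, VOCAB.modification)
            )
            base = Base(
                name=lit(b_uri, VOCAB.name),
                anomer=lit(b_uri, VOCAB.anomer, "x"),
                anomeric_carbon=parse_position(lit(b_uri, VOCAB.anomericCarbon, "-1")),
                parent_anomeric_carbon=parse_position(lit(b_uri, VOCAB.parentAnomericCarbon, "-1")),
                ring=(
                    UNKNOWN if ring_tok[0] == "x" else int(ring_tok[0]),
                    UNKNOWN if ring_tok[1] == "x" else int(ring_tok[1]),
                ),
                modifications=mods,
            )
        sub = None
        s_uri = g.value(r_uri, VOCAB.hasSubstituent)
        if s_uri is not None:
            sub = Substituent(
                name=lit(s_uri, VOCAB.name),
                attach_position_on_base=parse_position(lit(s_uri, VOCAB.attachPosition, "-1")),
                child_position=parse_position(lit(s_uri, VOCAB.childPosition, "-1")),
            )
        residue = Residue(
            id=rid,
            base=base,
            substituent=sub,
            composition=lit(r_uri, VOCAB.composition),
            is_root=is_root,
        )
        for c_uri in g.objects(r_uri, VOCAB.hasChildResidue):
            link = Linkage(
                parent_bond=lit(c_uri, VOCAB.linkageParentBond, "o"),
                child_bond=lit(c_uri, VOCAB.linkageChildBond, "d"),
                parent_positions=parse_positions(lit(c_uri, VOCAB.linkageParentPositions, "-1")),
                child_positions=parse_positions(lit(c_uri, VOCAB.linkageChildPositions, "-1")),
            )
            residue.children.append((link, read_residue(c_uri, is_root=False)))
        return residue

    core = None
    core_uri = g.value(glycan_uri, VOCAB.hasGlycanCore)
    if core_uri is not None:
        root = read_residue(g.value(core_uri, VOCAB.hasRootResidue), is_root=True)
        core = GlycanCore(root=root)

    bag = None
    bag_uri = g.value(glycan_uri, VOCAB.hasGlycanBag)
    if bag_uri is not None:
        items = []
        for it_uri in g.objects(bag_uri, VOCAB.hasItem):
            ordinal = int(lit(it_uri, VOCAB.ordinal))
            root = read_residue(g.value(it_uri, VOCAB.hasRootResidue), is_root=True)
            candidates = frozenset(
                int(str(c)) for c in g.objects(it_uri, VOCAB.parentCandidate)
            )
            weights = (
                float(lit(it_uri, VOCAB.majorWeight, "100.0")),
                float(lit(it_uri, VOCAB.minorWeight, "100.0")),
            )
            items.append(GlycanBagItem(ordinal, root, candidates, weights))
        items.sort(key=lambda it: it.ordinal)
        bag = GlycanBag(items=items)

    return Glycan(id=gid, core=core, bag=bag)
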