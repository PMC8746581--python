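"""Synthetic GlycoCT corpora with controlled ambiguity and planted motifs.

Every other module is testable without any database download: this
generator grows random but chemically plausible glycan trees (roots drawn
from the common reducing-end residues, children attached at free carbons,
sialic acids only terminal, no two children on one carbon), emits valid
GlycoCT{condensed} text, and returns per-structure truth labels (planted
motif instances, planned bag sizes).

Ambiguity is controlled: glycosidic parent positions are blanked to "-1"
with probability ``p_unk``, anomers to "x" with their own probability, and
UND-block counts follow a configurable distribution whose default places a
bit over a quarter of structures in the "has undefined sections" class —
the ambiguity profile typical of curated glycan databases.

Benchmark corpora for motif search are generated with *rejection*: a
background structure that happens to contain the linkage-free Lewis probe
(checked with the exhaustive brute-force oracle, not with the production
matcher) is re-drawn, so the truth labels are exact by construction and a
matcher can be scored for sensitivity and specificity against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from glycantree.builder import build_glycan_indexed
from glycantree.errors import NoAttachmentPoint, UnknownToken
from glycantree.glycoct import parse_glycoct
from glycantree.model import Glycan, Residue
from glycantree.query import brute_force_match, library_pattern
from glycantree.rules import RuleSet, default_rules
from glycantree.util import UNKNOWN


# ---------------------------------------------------------------------------
# Vocabulary: how each common residue is written in GlycoCT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Entry:
    kind: str  # "base" | "composed" | "substituent"
    base_name: str = ""  # e.g. "dglc-HEX"
    ring: Tuple[int, int] = (1, 5)
    mods: frozenset = frozenset()
    sub_name: str = ""  # composed only
    sub_link: Tuple[int, int, str, str] = (0, 0, "", "")  # (pp, cp, pbond, cbond)
    anomeric: int = 1  # child-side carbon of a glycosidic bond
    free: Tuple[int, ...] = ()  # parent-side carbons open for children


_VOCAB: Dict[str, _Entry] = {
    "Glc": _Entry("base", "dglc-HEX", free=(2, 3, 4, 6)),
    "Gal": _Entry("base", "dgal-HEX", free=(2, 3, 4, 6)),
    "Man": _Entry("base", "dman-HEX", free=(2, 3, 4, 6)),
    "Fuc": _Entry("base", "lgal-HEX", mods=frozenset({(6, "d")}), free=(2, 3, 4)),
    "Xyl": _Entry("base", "dxyl-PEN", free=(2, 3, 4)),
    "GlcNAc": _Entry(
        "composed", "dglc-HEX", sub_name="n-acetyl", sub_link=(2, 1, "d", "n"), free=(3, 4, 6)
    ),
    "GalNAc": _Entry(
        "composed", "dgal-HEX", sub_name="n-acetyl", sub_link=(2, 1, "d", "n"), free=(3, 4, 6)
    ),
    "Neu5Ac": _Entry(
        "composed",
        "dgro-dgal-NON",
        ring=(2, 6),
        mods=frozenset({(1, "a"), (2, "keto"), (3, "d")}),
        sub_name="n-acetyl",
        sub_link=(5, 1, "d", "n"),
        anomeric=2,
        free=(),  # terminal only
    ),
    "phosphate": _Entry("substituent", sub_name="phosphate"),
    "sulfate": _Entry("substituent", sub_name="sulfate"),
}

_ROOT_NAMES = ("GlcNAc", "GalNAc", "Glc")


@dataclass
class NodeSpec:
    """One residue of a structure under construction."""

    name: str
    anomer: str = "b"
    parent_pos: object = None  # int | UNKNOWN; None at a root
    children: List["NodeSpec"] = field(default_factory=list)
    planted: bool = False
    blocked: set = field(default_factory=set)  # carbons spent on "-1" children

    @property
    def entry(self) -> _Entry:
        return _VOCAB[self.name]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def free_positions(self) -> List[int]:
        used = {c.parent_pos for c in self.children if c.parent_pos is not UNKNOWN}
        used |= self.blocked
        return [p for p in self.entry.free if p not in used]


@dataclass
class BagItemSpec:
    ordinal: int
    root: NodeSpec
    parent_candidates: List[NodeSpec] = field(default_factory=list)
    weights: Tuple[float, float] = (100.0, 100.0)


@dataclass
class StructureSpec:
    core: Optional[NodeSpec]
    bag_items: List[BagItemSpec] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Emission: spec tree → GlycoCT text
# ---------------------------------------------------------------------------


def _emit_structure(spec: StructureSpec) -> Tuple[str, Dict[int, int]]:
    """Emit GlycoCT text; returns (text, map id(NodeSpec) → emitted RES index)."""
    counter = [0]
    lin_counter = [0]
    node_index: Dict[int, int] = {}

    def emit_tree(root: NodeSpec) -> Tuple[List[str], List[str]]:
        res, lin = [], []

        def emit(node: NodeSpec) -> Tuple[int, str]:
            e = node.entry
            counter[0] += 1
            idx = counter[0]
            node_index[id(node)] = idx
            if e.kind == "substituent":
                res.append(f"{idx}s:{e.sub_name}")
                return idx, "n"
            ring = f"{e.ring[0]}:{e.ring[1]}"
            mods = "".join(f"|{p}:{k}" for p, k in sorted(e.mods))
            res.append(f"{idx}b:{node.anomer}-{e.base_name}-{ring}{mods}")
            if e.kind == "composed":
                counter[0] += 1
                sidx = counter[0]
                res.append(f"{sidx}s:{e.sub_name}")
                pp, cp, pb, cb = e.sub_link
                lin_counter[0] += 1
                lin.append(f"{lin_counter[0]}:{idx}{pb}({pp}+{cp}){sidx}{cb}")
            for child in node.children:
                cidx, cbond = emit(child)
                ce = child.entry
                pos = "-1" if child.parent_pos is UNKNOWN else str(child.parent_pos)
                cpos = "1" if ce.kind == "substituent" else str(ce.anomeric)
                lin_counter[0] += 1
                lin.append(f"{lin_counter[0]}:{idx}o({pos}+{cpos}){cidx}{cbond}")
            return idx, "d"

        emit(root)
        return res, lin

    lines: List[str] = ["RES"]
    main_lin: List[str] = []
    if spec.core is not None:
        res, main_lin = emit_tree(spec.core)
        lines.extend(res)
    if main_lin:
        lines.append("LIN")
        lines.extend(main_lin)
    if spec.bag_items:
        lines.append("UND")
        for item in spec.bag_items:
            lines.append(f"UND{item.ordinal}:{item.weights[0]}:{item.weights[1]}")
            if item.parent_candidates:
                ids = sorted(node_index[id(n)] for n in item.parent_candidates)
                lines.append("ParentIDs:" + "|".join(str(i) for i in ids))
            cbond = "n" if item.root.entry.kind == "substituent" else "d"
            lines.append(f"SubtreeLinkageID1:o(-1+1){cbond}")
            res, lin = emit_tree(item.root)
            lines.append("RES")
            lines.extend(res)
            if lin:
                lines.append("LIN")
                lines.extend(lin)
    return "\n".join(lines), node_index


# ---------------------------------------------------------------------------
# Random growth
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    """Study conditions for synthetic corpora.

    Defaults emulate a curated-database ambiguity profile: moderate-size
    trees, ~15% unknown linkage positions and anomers, and UND sections on
    a bit over a quarter of structures.
    """

    n_structures: int = 200
    residue_range: Tuple[int, int] = (2, 7)
    alphabet: Dict[str, float] = field(
        default_factory=lambda: {
            "Glc": 0.10,
            "Gal": 0.16,
            "Man": 0.14,
            "GlcNAc": 0.18,
            "GalNAc": 0.08,
            "Fuc": 0.10,
            "Neu5Ac": 0.08,
            "Xyl": 0.04,
            "phosphate": 0.06,
            "sulfate": 0.06,
        }
    )
    branching_probability: float = 0.4
    p_unk: float = 0.15
    unknown_anomer_probability: float = 0.15
    und_distribution: Dict[int, float] = field(
        default_factory=lambda: {
            0: 0.72, 1: 0.10, 2: 0.07, 3: 0.05, 4: 0.03,
            5: 0.015, 6: 0.007, 7: 0.004, 8: 0.003, 9: 0.001,
        }
    )
    seed: int = 0

    def __post_init__(self):
        for p in (self.branching_probability, self.p_unk, self.unknown_anomer_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for dist in (self.alphabet, self.und_distribution):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"distribution does not normalize (sum={total})")


@dataclass
class TruthLabels:
    structure_id: str
    motifs: List[Tuple[str, Tuple[int, ...]]] = field(default_factory=list)
    planned_bag_size: int = 0

    @property
    def is_positive(self) -> bool:
        return bool(self.motifs)


def _choose(rng: np.random.Generator, dist: Dict) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _anomer(rng: np.random.Generator, params: GeneratorParams) -> str:
    if rng.random() < params.unknown_anomer_probability:
        return "x"
    return "a" if rng.random() < 0.5 else "b"


def _grow_tree(
    rng: np.random.Generator, params: GeneratorParams, n_residues: int, root_name: str
) -> NodeSpec:
    root = NodeSpec(root_name, anomer=_anomer(rng, params))
    nodes = [root]
    last = root
    while sum(1 for _ in root.walk()) < n_residues:
        open_nodes = [n for n in nodes if n.free_positions()]
        if not open_nodes:
            break
        if last in open_nodes and rng.random() >= params.branching_probability:
            parent = last  # chain growth
        else:
            parent = open_nodes[int(rng.integers(len(open_nodes)))]
        name = _choose(rng, params.alphabet)
        free = parent.free_positions()
        pos = int(free[int(rng.integers(len(free)))])
        if rng.random() < params.p_unk:
            pos_final: object = UNKNOWN
            # an unknown-position child still occupies a carbon: block the
            # drawn one so no sibling lands on it explicitly
            parent.blocked.add(pos)
        else:
            pos_final = pos
        child = NodeSpec(name, anomer=_anomer(rng, params), parent_pos=pos_final)
        parent.children.append(child)
        nodes.append(child)
        last = child
    return root


def _random_structure_spec(rng: np.random.Generator, params: GeneratorParams) -> StructureSpec:
    lo, hi = params.residue_range
    n = int(rng.integers(lo, hi + 1))
    root_name = _ROOT_NAMES[int(rng.integers(len(_ROOT_NAMES)))]
    core = _grow_tree(rng, params, n, root_name)
    n_items = int(_choose(rng, params.und_distribution))
    items = []
    core_bases = [nd for nd in core.walk() if nd.entry.kind != "substituent"]
    for ordinal in range(1, n_items + 1):
        size = int(rng.integers(1, 4))
        item_root_name = _choose(rng, params.alphabet)
        if _VOCAB[item_root_name].kind == "substituent":
            item_root = NodeSpec(item_root_name)
        else:
            item_root = _grow_tree(rng, params, size, item_root_name)
        k = int(rng.integers(0, min(2, len(core_bases)) + 1))
        cands = list(rng.choice(len(core_bases), size=k, replace=False)) if k else []
        items.append(
            BagItemSpec(
                ordinal=ordinal,
                root=item_root,
                parent_candidates=[core_bases[int(i)] for i in cands],
            )
        )
    return StructureSpec(core=core, bag_items=items)


def _build_from_spec(
    spec: StructureSpec, rules: RuleSet, structure_id: str
) -> Tuple[Glycan, str, Dict[int, int]]:
    """Emit, parse and build; returns (glycan, text, map id(NodeSpec) → residue id)."""
    text, node_index = _emit_structure(spec)
    glycan, index_to_id = build_glycan_indexed(parse_glycoct(text), rules, id=structure_id)
    node_to_residue = {
        nid: index_to_id[idx] for nid, idx in node_index.items() if idx in index_to_id
    }
    return glycan, text, node_to_residue


def random_glycan(
    params: GeneratorParams, seed: Optional[int] = None, structure_id: str = "S1",
    rules: Optional[RuleSet] = None,
) -> Tuple[Glycan, str, TruthLabels]:
    """One random structure: (built Glycan, GlycoCT text, truth labels)."""
    rules = rules or default_rules()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    spec = _random_structure_spec(rng, params)
    glycan, text, _ = _build_from_spec(spec, rules, structure_id)
    labels = TruthLabels(structure_id=structure_id, planned_bag_size=len(spec.bag_items))
    return glycan, text, labels


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

# concrete instances of the built-in library motifs, as (name, anomer,
# parent position, children) templates; the instance root attaches to the
# host at a free carbon
_MOTIF_TEMPLATES: Dict[str, dict] = {
    "lewis_a": {
        "name": "GlcNAc", "anomer": "b",
        "children": [
            {"name": "Gal", "anomer": "b", "pos": 3, "children": []},
            {"name": "Fuc", "anomer": "a", "pos": 4, "children": []},
        ],
    },
    "lewis_x": {
        "name": "GlcNAc", "anomer": "b",
        "children": [
            {"name": "Gal", "anomer": "b", "pos": 4, "children": []},
            {"name": "Fuc", "anomer": "a", "pos": 3, "children": []},
        ],
    },
    "lewis_b": {
        "name": "GlcNAc", "anomer": "b",
        "children": [
            {"name": "Gal", "anomer": "b", "pos": 3,
             "children": [{"name": "Fuc", "anomer": "a", "pos": 2, "children": []}]},
            {"name": "Fuc", "anomer": "a", "pos": 4, "children": []},
        ],
    },
    "lewis_y": {
        "name": "GlcNAc", "anomer": "b",
        "children": [
            {"name": "Gal", "anomer": "b", "pos": 4,
             "children": [{"name": "Fuc", "anomer": "a", "pos": 2, "children": []}]},
            {"name": "Fuc", "anomer": "a", "pos": 3, "children": []},
        ],
    },
}


def _instantiate(template: dict, parent_pos) -> NodeSpec:
    node = NodeSpec(template["name"], anomer=template["anomer"], parent_pos=parent_pos, planted=True)
    for child in template["children"]:
        node.children.append(_instantiate(child, child["pos"]))
    return node


def _spec_from_glycan(glycan: Glycan) -> StructureSpec:
    """Recover the generator's spec tree from a built Glycan (vocabulary names)."""

    def name_of(r: Residue) -> str:
        if r.base is None:
            if r.substituent.name in _VOCAB:
                return r.substituent.name
            raise UnknownToken(f"residue with substituent {r.substituent.name!r} not in vocabulary")
        mods = set(r.base.modifications)
        if r.substituent is not None:
            for name, e in _VOCAB.items():
                if (
                    e.kind == "composed"
                    and e.base_name == r.base.name
                    and e.sub_name == r.substituent.name
                ):
                    return name
            raise UnknownToken(f"composed {r.base.name}+{r.substituent.name} not in vocabulary")
        # base-only: the entry with the most required modifications wins
        # (Fuc = lgal-HEX|6:d beats a hypothetical plain lgal-HEX entry)
        candidates = [
            (len(e.mods), name)
            for name, e in _VOCAB.items()
            if e.kind == "base" and e.base_name == r.base.name and e.mods <= mods
        ]
        if not candidates:
            raise UnknownToken(f"residue {r.base.name!r} not in generator vocabulary")
        return max(candidates)[1]

    def convert(r: Residue, parent_pos) -> NodeSpec:
        node = NodeSpec(name_of(r), anomer=(r.base.anomer if r.base else "b"), parent_pos=parent_pos)
        for link, child in r.children:
            ps = link.parent_positions
            pos = next(iter(ps)) if len(ps) == 1 else UNKNOWN
            node.children.append(convert(child, pos))
        return node

    core = convert(glycan.core.root, None) if glycan.core else None
    items = []
    if glycan.bag:
        for it in sorted(glycan.bag.items, key=lambda i: i.ordinal):
            items.append(BagItemSpec(ordinal=it.ordinal, root=convert(it.root, None), weights=it.weights))
    return StructureSpec(core=core, bag_items=items)


def plant_pattern(
    glycan: Glycan,
    pattern_id: str,
    blank_linkages: bool = False,
    seed: int = 0,
    rules: Optional[RuleSet] = None,
) -> Tuple[Glycan, TruthLabels]:
    """Graft a concrete instance of a library motif onto a random free carbon.

    With ``blank_linkages`` a random non-empty subset of the instance's
    glycosidic positions (and the corresponding anomers) is set to unknown,
    producing a structure that a strict pattern misses but the linkage-free
    fuzzy probe still finds.
    """
    if pattern_id not in _MOTIF_TEMPLATES:
        raise UnknownToken(f"no planting template for pattern {pattern_id!r}")
    rules = rules or default_rules()
    rng = np.random.default_rng(seed)
    spec = _spec_from_glycan(glycan)
    if spec.core is None:
        raise NoAttachmentPoint("glycan has no core to graft onto")
    acceptors = [
        n for n in spec.core.walk() if n.entry.kind != "substituent" and n.free_positions()
    ]
    if not acceptors:
        raise NoAttachmentPoint("no residue with a free carbon accepts the motif")
    host = acceptors[int(rng.integers(len(acceptors)))]
    free = host.free_positions()
    pos = int(free[int(rng.integers(len(free)))])
    instance = _instantiate(_MOTIF_TEMPLATES[pattern_id], pos)
    host.children.append(instance)

    if blank_linkages:
        planted = [n for n in instance.walk()]
        mask = rng.random(len(planted)) < 0.5
        if not mask.any():
            mask[int(rng.integers(len(planted)))] = True
        for node, blank in zip(planted, mask):
            if blank:
                node.parent_pos = UNKNOWN
                node.anomer = "x"

    new_glycan, _, node_to_residue = _build_from_spec(spec, rules, glycan.id)
    planted_ids = tuple(
        sorted(node_to_residue[id(n)] for n in instance.walk())
    )
    labels = TruthLabels(
        structure_id=glycan.id,
        motifs=[(pattern_id, planted_ids)],
        planned_bag_size=len(spec.bag_items),
    )
    return new_glycan, labels


# ---------------------------------------------------------------------------
# Benchmark corpora
# ---------------------------------------------------------------------------


def make_benchmark(
    n: int,
    motif_frequency: float,
    p_unk: float = 0.15,
    seed: int = 0,
    rules: Optional[RuleSet] = None,
) -> Tuple[List[Tuple[str, str]], List[Glycan], List[TruthLabels]]:
    """A labeled corpus for motif-search scoring.

    ``round(n * motif_frequency)`` structures get a Lewis B or Y instance
    planted (half of them with blanked linkages); the rest are guaranteed
    negatives by rejection against the linkage-free Lewis probe using the
    brute-force oracle.  Returns (records, built glycans, labels).
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rules = rules or default_rules()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    probe = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy", scope="both")

    n_pos = int(round(n * motif_frequency))
    positives = set(master.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()

    records: List[Tuple[str, str]] = []
    glycans: List[Glycan] = []
    labels: List[TruthLabels] = []
    struct_seeds = ss.spawn(n)
    for i in range(n):
        sid = f"S{i + 1:04d}"
        rng_i = np.random.default_rng(struct_seeds[i])
        params = GeneratorParams(p_unk=p_unk, seed=0)
        # rejection: background must not contain the probe motif by chance
        for attempt in range(50):
            spec = _random_structure_spec(rng_i, params)
            glycan, text, _ = _build_from_spec(spec, rules, sid)
            if not brute_force_match(probe, glycan, guard=40):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a motif-free background structure")
        label = TruthLabels(structure_id=sid, planned_bag_size=len(spec.bag_items))
        if i in positives:
            motif = "lewis_b" if rng_i.random() < 0.5 else "lewis_y"
            blank = bool(rng_i.random() < 0.5)
            glycan, label = plant_pattern(
                glycan, motif, blank_linkages=blank, seed=int(rng_i.integers(2**31)), rules=rules
            )
            # re-emit so the corpus text matches the planted structure; the
            # deterministic id assignment keeps the label residue ids valid
            glycan, text, _ = _build_from_spec(_spec_from_glycan(glycan), rules, sid)
        records.append((sid, text))
        glycans.append(glycan)
        labels.append(label)
    return records, glycans, labels


def write_manifest(path, labels: Sequence[TruthLabels]) -> None:
    """Labels manifest TSV: structure_id, motif_id, residue_ids, bag_size."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("structure_id\tmotif_id\tresidue_ids\tbag_size\n")
        for lab in labels:
            if lab.motifs:
                for motif_id, rids in lab.motifs:
                    ids = ";".join(str(r) for r in rids)
                    fh.write(f"{lab.structure_id}\t{motif_id}\t{ids}\t{lab.planned_bag_size}\n")
            else:
                fh.write(f"{lab.structure_id}\t-\t-\t{lab.planned_bag_size}\n")
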