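"""Translate raw GlycoCT sections into the tree+bag model.

Pipeline per structure:

1. turn RES entries into single-block nodes and LIN entries into edges;
2. merge base+substituent pairs into composed residues where a
   composed-residue rule fires (only on fully explicit carbon positions);
3. assign every residue its composition class (composed residues take the
   rule's class, single blocks go through the composition table);
4. build one bag item per UND block with the same procedure, remapping
   attachment-candidate RES indices to model residue ids.

Residue ids are assigned in deterministic core preorder followed by bag
items in ordinal order, so rebuilding the same input always yields the same
ids (stable RDF URIs and match reports).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from glycantree.errors import AmbiguousRoot, ConflictingMerge
from glycantree.glycoct import (
    RawBase,
    RawLinkage,
    RawStructure,
    RawSubstituent,
    RawUndBlock,
)
from glycantree.model import (
    Base,
    Glycan,
    GlycanBag,
    GlycanBagItem,
    GlycanCore,
    Linkage,
    Residue,
    Substituent,
    _child_sort_key,
)
from glycantree.rules import RuleSet, composition_of, match_composed_rule
from glycantree.util import UNKNOWN, positions_sort_key


def _model_linkage(raw: RawLinkage) -> Linkage:
    return Linkage(
        parent_bond=raw.parent_bond,
        child_bond=raw.child_bond,
        parent_positions=raw.parent_positions,
        child_positions=raw.child_positions,
    )


def _single_position(positions):
    if len(positions) == 1:
        (p,) = positions
        return p
    return UNKNOWN


def merge_composed(
    res_entries, lin_entries, rules: RuleSet
) -> Tuple[Dict[int, Residue], List[Tuple[int, Linkage, int]], Dict[int, int]]:
    """Merge rule-matching base→substituent edges into composed residues.

    Returns (nodes by RES index, surviving edges as (parent_idx, Linkage,
    child_idx), and a map RES index → owning RES index for merged
    substituents).  Merging is confluent: each substituent has exactly one
    parent in a tree, and when several substituent children of one base
    match rules, only the lowest-keyed edge (by parent position, then child
    index) merges — a residue hosts at most one substituent.
    """
    entries = {e.index: e for e in res_entries}
    # decide merges deterministically
    candidate_edges = []
    for lin in lin_entries:
        parent = entries[lin.parent_index]
        child = entries[lin.child_index]
        if isinstance(parent, RawBase) and isinstance(child, RawSubstituent):
            base = Base(name=parent.name, anomer=parent.anomer, ring=parent.ring,
                        modifications=parent.modifications)
            sub = _sub_from_raw(child)
            rule = match_composed_rule(base, sub, _model_linkage(lin), rules)
            if rule is not None:
                candidate_edges.append((lin, rule))
    candidate_edges.sort(
        key=lambda t: (t[0].parent_index, positions_sort_key(t[0].parent_positions), t[0].child_index)
    )
    merged_into: Dict[int, int] = {}  # substituent idx -> base idx
    merge_rule: Dict[int, object] = {}
    merge_link: Dict[int, RawLinkage] = {}
    bases_taken = set()
    for lin, rule in candidate_edges:
        if lin.child_index in merged_into:
            raise ConflictingMerge(
                f"substituent {lin.child_index} matched composed rules on two edges"
            )
        if lin.parent_index in bases_taken:
            continue  # residue already hosts a substituent; keep this one separate
        merged_into[lin.child_index] = lin.parent_index
        merge_rule[lin.parent_index] = rule
        merge_link[lin.parent_index] = lin
        bases_taken.add(lin.parent_index)

    # build residue nodes
    nodes: Dict[int, Residue] = {}
    owner: Dict[int, int] = {}
    for idx, entry in entries.items():
        owner[idx] = merged_into.get(idx, idx)
        if idx in merged_into:
            continue  # consumed by a composed residue
        if isinstance(entry, RawBase):
            base = Base(
                name=entry.name,
                anomer=entry.anomer,
                ring=entry.ring,
                modifications=entry.modifications,
            )
            sub = None
            if idx in merge_rule:
                rule = merge_rule[idx]
                sub_entry = entries[merge_link[idx].child_index]
                sub = _sub_from_raw(sub_entry)
                sub.attach_position_on_base = rule.first_carbon
                sub.child_position = rule.second_carbon
                comp = rule.composition_class
            else:
                comp = composition_of(base, rules)
            nodes[idx] = Residue(id=-1, base=base, substituent=sub, composition=comp)
        else:
            sub = _sub_from_raw(entry)
            nodes[idx] = Residue(id=-1, substituent=sub, composition=composition_of(sub, rules))

    # surviving edges (re-parent any children of merged substituents)
    edges: List[Tuple[int, Linkage, int]] = []
    for lin in lin_entries:
        if merged_into.get(lin.child_index) == lin.parent_index:
            continue  # the consumed base→substituent edge
        parent = owner[lin.parent_index]
        child = owner[lin.child_index]
        edges.append((parent, _model_linkage(lin), child))
    return nodes, edges, owner


def _sub_from_raw(entry: RawSubstituent) -> Substituent:
    return Substituent(name=entry.name)


def _build_tree(res_entries, lin_entries, rules: RuleSet, what: str):
    """Build one rooted residue tree from a RES/LIN pair.

    Returns (root residue, owner map RES index → representative RES index,
    nodes by representative index).
    """
    nodes, edges, owner = merge_composed(res_entries, lin_entries, rules)
    has_parent = set()
    for parent_idx, link, child_idx in edges:
        child = nodes[child_idx]
        nodes[parent_idx].children.append((link, child))
        has_parent.add(child_idx)
        if child.base is not None:
            child.base.anomeric_carbon = _single_position(link.child_positions)
            child.base.parent_anomeric_carbon = _single_position(link.parent_positions)
        elif child.substituent is not None:
            child.substituent.child_position = _single_position(link.child_positions)
    roots = [idx for idx in nodes if idx not in has_parent]
    if len(roots) != 1:
        raise AmbiguousRoot(f"{what}: expected exactly one parentless residue, found {len(roots)}")
    root = nodes[roots[0]]
    root.is_root = True
    return root, owner, nodes


def _assign_ids(root: Residue, next_id: int) -> int:
    for residue in root.walk():
        residue.id = next_id
        next_id += 1
    # keep stored child order aligned with the deterministic walk order
    _sort_children(root)
    return next_id


def _sort_children(residue: Residue) -> None:
    residue.children.sort(key=_child_sort_key)
    for _, child in residue.children:
        _sort_children(child)


def build_glycan(raw: RawStructure, rules: RuleSet, id: str = "") -> Glycan:
    """Build a :class:`Glycan` from a parsed :class:`RawStructure`."""
    glycan, _ = build_glycan_indexed(raw, rules, id)
    return glycan


def build_glycan_indexed(
    raw: RawStructure, rules: RuleSet, id: str = ""
) -> Tuple[Glycan, Dict[int, int]]:
    """Like :func:`build_glycan`, also returning the map RES index → residue id.

    Merged substituent entries map to the id of the composed residue that
    consumed them.  Indices of UND-nested RES entries are included when they
    do not collide with main-section indices (GlycoCT numbers them globally).
    """
    core = None
    index_to_id: Dict[int, int] = {}
    next_id = 1
    main_owner: Dict[int, int] = {}
    if raw.res_entries:
        root, main_owner, nodes = _build_tree(raw.res_entries, raw.lin_entries, rules, "main section")
        core = GlycanCore(root=root)
        next_id = _assign_ids(root, next_id)
        for idx, rep in main_owner.items():
            index_to_id[idx] = nodes[rep].id

    bag = None
    if raw.und_blocks:
        items = []
        for blk in sorted(raw.und_blocks, key=lambda b: b.ordinal):
            root, owner, nodes = _build_tree(
                blk.res_entries, blk.lin_entries, rules, f"UND{blk.ordinal}"
            )
            next_id = _assign_ids(root, next_id)
            for idx, rep in owner.items():
                index_to_id.setdefault(idx, nodes[rep].id)
            candidates = frozenset(
                index_to_id[pid] for pid in blk.parent_candidate_ids if pid in main_owner
            )
            items.append(
                GlycanBagItem(
                    ordinal=blk.ordinal,
                    root=root,
                    parent_candidate_residue_ids=candidates,
                    weights=(blk.major_weight, blk.minor_weight),
                )
            )
        bag = GlycanBag(items=items)
    return Glycan(id=id, core=core, bag=bag), index_to_id


# ---------------------------------------------------------------------------
# Model → raw (canonical re-encoding, for round-trip checks and the generator)
# ---------------------------------------------------------------------------

_N_SUBSTITUENTS = {"n-acetyl", "n-glycolyl", "amino", "n-sulfate"}


def raw_from_glycan(glycan: Glycan) -> RawStructure:
    """Re-encode a built Glycan as a RawStructure (canonical index numbering).

    Composed residues are decomposed back into a base entry, a substituent
    entry and their linkage; N-linked substituents are re-emitted with the
    conventional d/n bond pair, others with o/n.
    """
    counter = [0]
    lin_counter = [0]

    def emit_tree(root: Residue):
        res, lin = [], []

        def emit(residue: Residue) -> int:
            counter[0] += 1
            idx = counter[0]
            if residue.base is not None:
                b = residue.base
                res.append(
                    RawBase(
                        index=idx,
                        anomer=b.anomer,
                        config_stem=_split_name(b.name)[0],
                        superclass=_split_name(b.name)[1],
                        ring=b.ring,
                        modifications=b.modifications,
                    )
                )
            else:
                res.append(RawSubstituent(index=idx, name=residue.substituent.name))
            if residue.is_composed:
                counter[0] += 1
                sub_idx = counter[0]
                s = residue.substituent
                res.append(RawSubstituent(index=sub_idx, name=s.name))
                lin_counter[0] += 1
                pb, cb = ("d", "n") if s.name in _N_SUBSTITUENTS else ("o", "n")
                lin.append(
                    RawLinkage(
                        index=lin_counter[0],
                        parent_index=idx,
                        parent_bond=pb,
                        parent_positions=frozenset({s.attach_position_on_base}),
                        child_index=sub_idx,
                        child_bond=cb,
                        child_positions=frozenset({s.child_position}),
                    )
                )
            for link, child in sorted(residue.children, key=_child_sort_key):
                child_idx = emit(child)
                lin_counter[0] += 1
                lin.append(
                    RawLinkage(
                        index=lin_counter[0],
                        parent_index=idx,
                        parent_bond=link.parent_bond,
                        parent_positions=link.parent_positions,
                        child_index=child_idx,
                        child_bond=link.child_bond,
                        child_positions=link.child_positions,
                    )
                )
            return idx

        emit(root)
        return res, lin

    main_res, main_lin = ([], [])
    if glycan.core is not None:
        main_res, main_lin = emit_tree(glycan.core.root)
    blocks = []
    if glycan.bag is not None:
        for item in sorted(glycan.bag.items, key=lambda it: it.ordinal):
            res, lin = emit_tree(item.root)
            blocks.append(
                RawUndBlock(
                    ordinal=item.ordinal,
                    major_weight=item.weights[0],
                    minor_weight=item.weights[1],
                    parent_candidate_ids=frozenset(),
                    subtree_linkage=None,
                    res_entries=tuple(res),
                    lin_entries=tuple(lin),
                )
            )
    return RawStructure(tuple(main_res), tuple(main_lin), tuple(blocks))


def _split_name(name: str):
    """Split a basetype string into (config_stem tuple, superclass)."""
    parts = name.split("-")
    superclass = parts[-1]
    stems = tuple((p[0], p[1:]) for p in parts[:-1])
    return stems, superclass


def build_corpus(records, rules: RuleSet) -> List[Glycan]:
    """Build Glycans from (structure_id, glycoct) records.

    An empty GlycoCT field yields an id-only Glycan (a structure with no
    structural encoding, hence neither core nor bag).
    """
    from glycantree.glycoct import parse_glycoct

    out = []
    for sid, text in records:
        if not text.strip():
            out.append(Glycan(id=sid))
        else:
            out.append(build_glycan(parse_glycoct(text), rules, id=sid))
    return out
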