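"""Composed-residue and composition rule systems.

Two editable rule tables drive model building:

* **Composed-residue rules** decide when a base+substituent pair connected
  by a fully specified linkage collapses into one residue (GlcNAc, GalNAc,
  Neu5Ac, ...), mirroring how such residues are drawn as a single SNFG
  symbol.  A rule has five fields: first block (base) name, second block
  (substituent) name, the two carbon numbers of their linkage, and the
  composition class of the merged residue.
* **Composition rules** assign a mass-isomer class (Hex, dHex, Pent,
  HexA, ...) to single building blocks.  A rule may require modifications
  (e.g. ``lgal-HEX|6:d`` — a 6-deoxy L-galactose, i.e. fucose — is dHex,
  while plain ``lgal-HEX`` is Hex); rules with modifications are more
  specific and win over name-only rules.

Rules are plain JSON: one array whose objects either carry the five
composed-rule keys (``first_block``, ``second_block``, ``first_carbon``,
``second_carbon``, ``composition``) or the two composition-rule keys
(``block``, ``composition``).  The shipped default table
(``data/default_rules.json``) covers the common animal donor residues and
can be replaced wholesale via :func:`load_rules` / the CLI ``--rules`` flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple, Union

from glycantree.errors import DuplicateRule, MissingField
from glycantree.model import Base, Linkage, Substituent
from glycantree.util import UNDEFINED, UNKNOWN

_COMPOSED_KEYS = ("first_block", "second_block", "first_carbon", "second_carbon", "composition")


@dataclass(frozen=True)
class ComposedResidueRule:
    first_block_name: str
    second_block_name: str
    first_carbon: int
    second_carbon: int
    composition_class: str

    @property
    def key(self) -> tuple:
        return (self.first_block_name, self.second_block_name, self.first_carbon, self.second_carbon)


@dataclass(frozen=True)
class CompositionRule:
    block_name: str  # basetype or substituent name
    required_modifications: frozenset  # of (position:int, kind:str)
    composition_class: str

    @property
    def key(self) -> tuple:
        return (self.block_name, self.required_modifications)


class RuleSet:
    """Loaded, validated rule tables with fast lookup."""

    def __init__(self, composed_rules: List[ComposedResidueRule], composition_rules: List[CompositionRule]):
        self.composed_rules = list(composed_rules)
        self.composition_rules = list(composition_rules)
        self._composed_index: Dict[tuple, ComposedResidueRule] = {}
        for r in self.composed_rules:
            if r.key in self._composed_index:
                raise DuplicateRule(f"duplicate composed rule for {r.key}")
            self._composed_index[r.key] = r
        self._composition_index: Dict[tuple, CompositionRule] = {}
        for r in self.composition_rules:
            if r.key in self._composition_index:
                raise DuplicateRule(f"duplicate composition rule for {r.key}")
            self._composition_index[r.key] = r

    def __repr__(self) -> str:
        return f"RuleSet(composed={len(self.composed_rules)}, composition={len(self.composition_rules)})"


def _parse_block_spec(spec: str) -> Tuple[str, frozenset]:
    """Split ``lgal-HEX|6:d`` into (name, required modifications)."""
    parts = spec.split("|")
    mods = []
    for tok in parts[1:]:
        pos, _, kind = tok.partition(":")
        mods.append((int(pos), kind))
    return parts[0], frozenset(mods)


def parse_rules(objects: List[dict]) -> RuleSet:
    """Build a RuleSet from a list of already-decoded JSON rule objects."""
    composed: List[ComposedResidueRule] = []
    composition: List[CompositionRule] = []
    for i, obj in enumerate(objects, start=1):
        if not obj or all(k.startswith("_") for k in obj):
            continue  # comment object
        if "first_block" in obj or "second_block" in obj:
            for k in _COMPOSED_KEYS:
                if k not in obj:
                    raise MissingField(i, k)
            composed.append(
                ComposedResidueRule(
                    obj["first_block"],
                    obj["second_block"],
                    int(obj["first_carbon"]),
                    int(obj["second_carbon"]),
                    obj["composition"],
                )
            )
        else:
            for k in ("block", "composition"):
                if k not in obj:
                    raise MissingField(i, k)
            name, mods = _parse_block_spec(obj["block"])
            composition.append(CompositionRule(name, mods, obj["composition"]))
    return RuleSet(composed, composition)


def load_rules(document: str) -> RuleSet:
    """Load a RuleSet from JSON text (one array of rule objects)."""
    data = json.loads(document)
    if not isinstance(data, list):
        raise MissingField(0, "top-level JSON array")
    return parse_rules(data)


def load_rules_file(path) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        return load_rules(fh.read())


_DEFAULT: Optional[RuleSet] = None


def default_rules() -> RuleSet:
    """The shipped default rule table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("glycantree").joinpath("data/default_rules.json").read_text()
        _DEFAULT = load_rules(text)
    return _DEFAULT


def _single_known_position(positions) -> Optional[int]:
    if len(positions) != 1:
        return None
    (p,) = positions
    return None if p is UNKNOWN else p


def match_composed_rule(
    base: Base, substituent: Substituent, link: Linkage, rules: RuleSet
) -> Optional[ComposedResidueRule]:
    """The unique composed rule keyed by (base name, substituent name, carbons), if any.

    A rule only fires on fully explicit single carbon positions: UNKNOWN or
    alternative ("3|6") positions never match.
    """
    p = _single_known_position(link.parent_positions)
    c = _single_known_position(link.child_positions)
    if p is None or c is None:
        return None
    return rules._composed_index.get((base.name, substituent.name, p, c))


def composition_of(block: Union[Base, Substituent], rules: RuleSet) -> str:
    """Composition class of a single building block; UNDEFINED when nothing matches.

    The most specific rule wins: a rule requiring modifications matches only
    if all its modifications are present on the block, and beats a name-only
    rule; among modification rules the one with most requirements wins.
    """
    if isinstance(block, Base):
        name, mods = block.name, {(p, k) for p, k in block.modifications if p is not UNKNOWN}
    else:
        name, mods = block.name, set()
    best: Optional[CompositionRule] = None
    for rule in rules.composition_rules:
        if rule.block_name != name:
            continue
        if not rule.required_modifications <= frozenset(mods):
            continue
        if best is None or len(rule.required_modifications) > len(best.required_modifications):
            best = rule
    return best.composition_class if best else UNDEFINED
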