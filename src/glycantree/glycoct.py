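"""GlycoCT{condensed} reading and writing.

This module deals only with the *wire format*: it turns GlycoCT text into a
raw section-level representation (``RawStructure``) and back, preserving
every token.  No model semantics (composed residues, compositions, bags as
model objects) happen here — that is the builder's job.

Dialect notes
-------------
* Targeted dialect: GlycoCT condensed with RES / LIN and optional UND
  sections.  REP (repeat units) and ALT sections are rejected with
  :class:`UnsupportedSection`; the XML flavour is out of scope.
* Unknown tokens are mapped to explicit sentinels, never silently
  defaulted: anomer ``x`` stays ``x``, position ``-1`` becomes
  ``{UNKNOWN}``, alternative positions ``3|6`` become ``{3, 6}``, ring
  bound ``x`` becomes ``UNKNOWN``.
* Blank lines and trailing whitespace are ignored; section headers must be
  exact uppercase tokens.
* A single-line form with spaces instead of newlines (the form used in
  tab-separated corpus files) is accepted by :func:`parse_glycoct`.

Corpus container
----------------
Multi-record corpora are tab-separated files with columns
``structure_id<TAB>glycoct`` where the GlycoCT newlines are encoded as
single spaces (GlycoCT tokens never contain spaces).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from glycantree.errors import (
    CyclicStructure,
    DanglingIndex,
    InvalidRaw,
    MalformedLine,
    UnsupportedSection,
)
from glycantree.util import (
    UNKNOWN,
    Position,
    PositionSet,
    format_position,
    format_positions,
    parse_position,
    parse_positions,
)

ANOMERS = frozenset("abxo")
SUPERCLASSES = frozenset({"TRI", "TET", "PEN", "HEX", "HEP", "OCT", "NON", "SUG"})
BOND_TYPES = frozenset("odnh")


# ---------------------------------------------------------------------------
# Raw section-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawBase:
    """One ``<n>b:`` RES entry (a monosaccharide skeleton)."""

    index: int
    anomer: str  # a / b / x (unknown) / o (open chain)
    config_stem: Tuple[Tuple[str, str], ...]  # ((configuration, stem), ...)
    superclass: str
    ring: Tuple[Position, Position]
    modifications: frozenset  # of (Position, kind)

    @property
    def name(self) -> str:
        """Basetype string used by the rule systems, e.g. ``dglc-HEX``."""
        stems = "-".join(c + s for c, s in self.config_stem)
        return f"{stems}-{self.superclass}" if stems else self.superclass


@dataclass(frozen=True)
class RawSubstituent:
    """One ``<n>s:`` RES entry (a non-sugar decoration)."""

    index: int
    name: str


@dataclass(frozen=True)
class RawLinkage:
    """One LIN entry: ``<n>:<parent><bond>(<ppos>+<cpos>)<child><bond>``."""

    index: int
    parent_index: int
    parent_bond: str
    parent_positions: PositionSet
    child_index: int
    child_bond: str
    child_positions: PositionSet


@dataclass(frozen=True)
class RawUndBlock:
    """One UND block: an unknown-linked subtree plus its attachment metadata."""

    ordinal: int
    major_weight: float
    minor_weight: float
    parent_candidate_ids: frozenset
    subtree_linkage: Optional[RawLinkage]  # parent/child indices unused (0)
    res_entries: Tuple[object, ...]  # RawBase | RawSubstituent
    lin_entries: Tuple[RawLinkage, ...]


@dataclass(frozen=True)
class RawStructure:
    res_entries: Tuple[object, ...]
    lin_entries: Tuple[RawLinkage, ...]
    und_blocks: Tuple[RawUndBlock, ...] = ()


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    line: int
    message: str


# ---------------------------------------------------------------------------
# Line parsers
# ---------------------------------------------------------------------------

_BASE_RE = re.compile(
    r"^(\d+)b:([abxo])"  # index, anomer
    r"((?:-[dlx][a-z]{3})*)"  # configuration+stem pairs, e.g. -dglc or -dgro-dgal
    r"-(TRI|TET|PEN|HEX|HEP|OCT|NON|SUG)"
    r"-([0-9x]+):([0-9x]+)"  # ring
    r"((?:\|[0-9x,]+:[a-z]+)*)$"  # modifications
)
_SUB_RE = re.compile(r"^(\d+)s:([a-z][a-z0-9-]*)$")
_LIN_RE = re.compile(
    r"^(\d+):(\d+)([odnh])\((-1|\d+(?:\|\d+)*)\+(-1|\d+(?:\|\d+)*)\)(\d+)([odnh])$"
)
_UND_HDR_RE = re.compile(r"^UND(\d+):([0-9.]+):([0-9.]+)$")
_PARENT_RE = re.compile(r"^ParentIDs:(\d+(?:\|\d+)*)$")
_SUBLINK_RE = re.compile(
    r"^SubtreeLinkageID(\d+):([odnh])\((-1|\d+(?:\|\d+)*)\+(-1|\d+(?:\|\d+)*)\)([odnh])$"
)


def _parse_base_line(line: str, line_no: int) -> RawBase:
    m = _BASE_RE.match(line)
    if not m:
        raise MalformedLine(line_no, f"not a valid base entry: {line!r}")
    index = int(m.group(1))
    anomer = m.group(2)
    config_stem = tuple(
        (tok[0], tok[1:]) for tok in m.group(3).split("-") if tok
    )
    superclass = m.group(4)
    ring = (_ring_bound(m.group(5)), _ring_bound(m.group(6)))
    mods = []
    for tok in m.group(7).split("|"):
        if not tok:
            continue
        pos_tok, kind = tok.split(":")
        # a modification like "2,3:en" names two carbons; keep one entry each
        for p in pos_tok.split(","):
            mods.append((parse_position(p), kind))
    if (
        ring[0] is not UNKNOWN
        and ring[1] is not UNKNOWN
        and ring[0] >= ring[1]
        and not (ring[0] == 0 and ring[1] == 0)
    ):
        raise MalformedLine(line_no, f"ring start must precede ring end: {line!r}")
    return RawBase(index, anomer, config_stem, superclass, ring, frozenset(mods))


def _ring_bound(tok: str) -> Position:
    return UNKNOWN if tok == "x" else int(tok)


def _parse_sub_line(line: str, line_no: int) -> RawSubstituent:
    m = _SUB_RE.match(line)
    if not m:
        raise MalformedLine(line_no, f"not a valid substituent entry: {line!r}")
    return RawSubstituent(int(m.group(1)), m.group(2))


def _parse_res_line(line: str, line_no: int):
    if "b:" in line.split(":", 1)[0] + ":" and re.match(r"^\d+b:", line):
        return _parse_base_line(line, line_no)
    if re.match(r"^\d+s:", line):
        return _parse_sub_line(line, line_no)
    raise MalformedLine(line_no, f"not a RES entry: {line!r}")


def _parse_lin_line(line: str, line_no: int) -> RawLinkage:
    m = _LIN_RE.match(line)
    if not m:
        raise MalformedLine(line_no, f"not a valid LIN entry: {line!r}")
    return RawLinkage(
        index=int(m.group(1)),
        parent_index=int(m.group(2)),
        parent_bond=m.group(3),
        parent_positions=parse_positions(m.group(4)),
        child_index=int(m.group(6)),
        child_bond=m.group(7),
        child_positions=parse_positions(m.group(5)),
    )


# ---------------------------------------------------------------------------
# Structure-level parsing
# ---------------------------------------------------------------------------


def _normalize_lines(text: str) -> List[Tuple[int, str]]:
    """Split into (line_no, stripped line), accepting the one-line space form."""
    if "\n" not in text and " " in text:
        raw_lines = text.split(" ")
    else:
        raw_lines = text.split("\n")
    out = []
    for i, ln in enumerate(raw_lines, start=1):
        s = ln.strip()
        if s:
            out.append((i, s))
    return out


def parse_glycoct(text: str) -> RawStructure:
    """Parse GlycoCT{condensed} text into a :class:`RawStructure`.

    Raises :class:`MalformedLine`, :class:`UnsupportedSection`,
    :class:`DanglingIndex`, :class:`CyclicStructure` or :class:`InvalidRaw`.
    """
    lines = _normalize_lines(text)
    if not lines or lines[0][1] != "RES":
        raise MalformedLine(lines[0][0] if lines else 1, "text must start with a RES header")
    for no, ln in lines:
        if ln in ("REP", "ALT") or re.match(r"^REP\d+:", ln) or re.match(r"^ALT\d+:", ln):
            raise UnsupportedSection(
                f"line {no}: {ln.split(':')[0]} sections (repeat/alternative units) are not supported"
            )

    # split into main part and UND part
    und_start = next((i for i, (_, ln) in enumerate(lines) if ln == "UND"), None)
    main = lines[1:und_start] if und_start is not None else lines[1:]
    und_lines = lines[und_start + 1 :] if und_start is not None else []

    res_entries, lin_entries = _parse_res_lin(main)
    und_blocks = _parse_und(und_lines)

    raw = RawStructure(tuple(res_entries), tuple(lin_entries), tuple(und_blocks))
    _check_structure(raw)
    return raw


def _parse_res_lin(lines: Sequence[Tuple[int, str]]):
    res, lin = [], []
    section = "RES"
    for no, ln in lines:
        if ln == "LIN":
            section = "LIN"
            continue
        if ln == "RES":
            raise MalformedLine(no, "unexpected RES header")
        if section == "RES":
            res.append(_parse_res_line(ln, no))
        else:
            lin.append(_parse_lin_line(ln, no))
    return res, lin


def _parse_und(lines: Sequence[Tuple[int, str]]) -> List[RawUndBlock]:
    blocks: List[RawUndBlock] = []
    i = 0
    warnings: List[str] = []
    while i < len(lines):
        no, ln = lines[i]
        m = _UND_HDR_RE.match(ln)
        if not m:
            raise MalformedLine(no, f"expected UND block header, got {ln!r}")
        ordinal = int(m.group(1))
        major, minor = float(m.group(2)), float(m.group(3))
        if not (0 <= major <= 100 and 0 <= minor <= 100):
            raise MalformedLine(no, "UND weights must be percentages in [0, 100]")
        i += 1
        parent_ids: frozenset = frozenset()
        sublink: Optional[RawLinkage] = None
        body: List[Tuple[int, str]] = []
        while i < len(lines) and not _UND_HDR_RE.match(lines[i][1]):
            no2, ln2 = lines[i]
            pm = _PARENT_RE.match(ln2)
            sm = _SUBLINK_RE.match(ln2)
            if pm:
                parent_ids = frozenset(int(t) for t in pm.group(1).split("|"))
            elif sm:
                link = RawLinkage(
                    index=int(sm.group(1)),
                    parent_index=0,
                    parent_bond=sm.group(2),
                    parent_positions=parse_positions(sm.group(3)),
                    child_index=0,
                    child_bond=sm.group(5),
                    child_positions=parse_positions(sm.group(4)),
                )
                if sublink is None:
                    sublink = link
                # extra SubtreeLinkage entries are stored nowhere; the model
                # keeps only the first (attachment stays unknown either way)
            else:
                body.append((no2, ln2))
            i += 1
        if not body or body[0][1] != "RES":
            raise MalformedLine(no, f"UND{ordinal} block lacks a nested RES section")
        res, lin = _parse_res_lin(body[1:])
        if not res:
            raise MalformedLine(no, f"UND{ordinal} nested RES section is empty")
        blocks.append(
            RawUndBlock(ordinal, major, minor, parent_ids, sublink, tuple(res), tuple(lin))
        )
    return blocks


def _check_res_lin(res_entries, lin_entries, what: str) -> None:
    indices = [e.index for e in res_entries]
    if len(set(indices)) != len(indices):
        raise InvalidRaw(f"duplicate RES indices in {what}")
    index_set = set(indices)
    parents = {}
    for ln in lin_entries:
        for ref in (ln.parent_index, ln.child_index):
            if ref not in index_set:
                raise DanglingIndex(f"LIN {ln.index} in {what} references missing RES index {ref}")
        if ln.parent_index == ln.child_index:
            raise CyclicStructure(f"LIN {ln.index} in {what} links an entry to itself")
        if ln.child_index in parents:
            raise CyclicStructure(
                f"RES {ln.child_index} in {what} has two parents (not a tree)"
            )
        parents[ln.child_index] = ln.parent_index
    # cycle check by walking to the root from every node
    for start in parents:
        seen = set()
        node = start
        while node in parents:
            if node in seen:
                raise CyclicStructure(f"linkage cycle in {what} involving RES {node}")
            seen.add(node)
            node = parents[node]
    if res_entries:
        roots = [i for i in indices if i not in parents]
        if len(roots) != 1:
            raise InvalidRaw(
                f"{what} must form a single tree with one root; found {len(roots)} parentless entries"
            )


def _check_structure(raw: RawStructure) -> None:
    # a composition-only structure may have an empty main section, but only
    # if UND blocks carry the residues
    if not raw.res_entries and not raw.und_blocks:
        raise InvalidRaw("empty RES section")
    _check_res_lin(raw.res_entries, raw.lin_entries, "main section")
    main_indices = {e.index for e in raw.res_entries}
    seen_ordinals = set()
    for blk in raw.und_blocks:
        if blk.ordinal in seen_ordinals:
            raise InvalidRaw(f"duplicate UND ordinal {blk.ordinal}")
        seen_ordinals.add(blk.ordinal)
        _check_res_lin(blk.res_entries, blk.lin_entries, f"UND{blk.ordinal}")
        for pid in blk.parent_candidate_ids:
            if pid not in main_indices:
                raise DanglingIndex(
                    f"UND{blk.ordinal} ParentIDs references missing RES index {pid}"
                )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _format_base(b: RawBase) -> str:
    stems = "".join(f"-{c}{s}" for c, s in b.config_stem)
    ring = f"{_fmt_ring(b.ring[0])}:{_fmt_ring(b.ring[1])}"
    mods = "".join(
        f"|{format_position(p)}:{k}"
        for p, k in sorted(b.modifications, key=lambda m: (str(m[0]), m[1]))
    )
    return f"{b.index}b:{b.anomer}{stems}-{b.superclass}-{ring}{mods}"


def _fmt_ring(p: Position) -> str:
    return "x" if p is UNKNOWN else str(p)


def _format_lin(l: RawLinkage) -> str:
    return (
        f"{l.index}:{l.parent_index}{l.parent_bond}"
        f"({format_positions(l.parent_positions)}+{format_positions(l.child_positions)})"
        f"{l.child_index}{l.child_bond}"
    )


def serialize_glycoct(raw: RawStructure) -> str:
    """Serialize a :class:`RawStructure` back to GlycoCT{condensed} text.

    Sections are emitted in RES, LIN, UND order, entries in ascending index
    order; output is bit-stable for a given input.
    """
    _check_structure(raw)  # raises InvalidRaw on violations
    out: List[str] = ["RES"]
    for e in sorted(raw.res_entries, key=lambda e: e.index):
        out.append(_format_base(e) if isinstance(e, RawBase) else f"{e.index}s:{e.name}")
    if raw.lin_entries:
        out.append("LIN")
        for l in sorted(raw.lin_entries, key=lambda l: l.index):
            out.append(_format_lin(l))
    if raw.und_blocks:
        out.append("UND")
        for blk in sorted(raw.und_blocks, key=lambda b: b.ordinal):
            out.append(f"UND{blk.ordinal}:{float(blk.major_weight)}:{float(blk.minor_weight)}")
            if blk.parent_candidate_ids:
                ids = "|".join(str(i) for i in sorted(blk.parent_candidate_ids))
                out.append(f"ParentIDs:{ids}")
            if blk.subtree_linkage is not None:
                sl = blk.subtree_linkage
                out.append(
                    f"SubtreeLinkageID{sl.index}:{sl.parent_bond}"
                    f"({format_positions(sl.parent_positions)}+{format_positions(sl.child_positions)})"
                    f"{sl.child_bond}"
                )
            out.append("RES")
            for e in sorted(blk.res_entries, key=lambda e: e.index):
                out.append(_format_base(e) if isinstance(e, RawBase) else f"{e.index}s:{e.name}")
            if blk.lin_entries:
                out.append("LIN")
                for l in sorted(blk.lin_entries, key=lambda l: l.index):
                    out.append(_format_lin(l))
    return "\n".join(out)


def validate_glycoct(text: str) -> List[Issue]:
    """Non-throwing validation: empty list iff :func:`parse_glycoct` succeeds."""
    try:
        parse_glycoct(text)
    except MalformedLine as e:
        return [Issue("error", e.line_no, e.reason)]
    except Exception as e:  # all other structured errors carry no line
        return [Issue("error", 0, str(e))]
    return []


# ---------------------------------------------------------------------------
# Corpus container (TSV: structure_id <TAB> space-encoded GlycoCT)
# ---------------------------------------------------------------------------


def encode_oneline(text: str) -> str:
    return " ".join(text.split())


def decode_oneline(oneline: str) -> str:
    return "\n".join(oneline.split(" "))


def read_corpus(path) -> List[Tuple[str, str]]:
    """Read a (structure_id, glycoct) TSV corpus; GlycoCT is newline-decoded."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, _, enc = line.partition("\t")
            records.append((sid, decode_oneline(enc)))
    return records


def write_corpus(path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, text in records:
            fh.write(f"{sid}\t{encode_oneline(text)}\n")
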