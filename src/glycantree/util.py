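"""Shared sentinels and position-set helpers.

Carbon positions are 1-based (GlycoCT convention).  An unknown position,
ring bound or anomer is represented by the :data:`UNKNOWN` singleton — never
by 0 or -1 internally; "-1" is only the wire token.
"""

from __future__ import annotations

from typing import FrozenSet, Union


class _Unknown:
    """Singleton sentinel for unknown positions/ring bounds."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __reduce__(self):
        return (_Unknown, ())


UNKNOWN = _Unknown()

#: Composition class assigned when no rule matches a building block.
UNDEFINED = "UNDEFINED"

Position = Union[int, _Unknown]
PositionSet = FrozenSet[Position]

#: The position set that encodes the GlycoCT "-1" token.
UNKNOWN_POSITIONS: PositionSet = frozenset({UNKNOWN})


def position_key(p: Position) -> int:
    """Sort key placing UNKNOWN after every concrete position."""
    return 10**6 if p is UNKNOWN else p


def format_position(p: Position) -> str:
    return "-1" if p is UNKNOWN else str(p)


def parse_position(token: str) -> Position:
    token = token.strip()
    if token in ("-1", "x", "X"):
        return UNKNOWN
    return int(token)


def format_positions(ps: PositionSet) -> str:
    """Inverse of :func:`parse_positions`: ``{UNKNOWN}`` → ``-1``, ``{3,6}`` → ``3|6``."""
    if ps == UNKNOWN_POSITIONS:
        return "-1"
    return "|".join(str(p) for p in sorted(ps, key=position_key))


def parse_positions(token: str) -> PositionSet:
    """Parse a GlycoCT position token: ``-1`` (unknown) or ``3|6`` (alternatives)."""
    token = token.strip()
    if token == "-1":
        return UNKNOWN_POSITIONS
    parts = [parse_position(t) for t in token.split("|")]
    return frozenset(parts)


def positions_sort_key(ps: PositionSet) -> tuple:
    return tuple(sorted(position_key(p) for p in ps))
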