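"""Exception hierarchy for the package.

All parsing/model errors derive from :class:`GlycoCTError` so callers can
catch a single type at pipeline boundaries (the CLI maps them to exit 1).
"""


class GlycoCTError(ValueError):
    """Base class for all structured errors raised by this package."""


class MalformedLine(GlycoCTError):
    """A GlycoCT line does not match the condensed grammar."""

    def __init__(self, line_no: int, reason: str):
        self.line_no = line_no
        self.reason = reason
        super().__init__(f"line {line_no}: {reason}")


class UnsupportedSection(GlycoCTError):
    """Section present that the model does not cover (REP/ALT/XML forms)."""


class DanglingIndex(GlycoCTError):
    """A LIN entry references a RES index that does not exist."""


class CyclicStructure(GlycoCTError):
    """The linkage graph contains a cycle (glycans are trees)."""


class InvalidRaw(GlycoCTError):
    """A RawStructure violates its invariants (empty RES, multiple roots...)."""


class AmbiguousRoot(GlycoCTError):
    """More than one parentless residue in a section that must be a tree."""


class ConflictingMerge(GlycoCTError):
    """A substituent would be consumed by two composed-residue merges."""


class DuplicateRule(GlycoCTError):
    """Two rules share the same key fields."""


class MissingField(GlycoCTError):
    """A rule object lacks a required field."""

    def __init__(self, ordinal: int, field: str):
        self.ordinal = ordinal
        self.field = field
        super().__init__(f"rule {ordinal}: missing field {field!r}")


class UnknownToken(GlycoCTError):
    """A pattern token cannot be resolved to a residue constraint."""


class UnbalancedBracket(GlycoCTError):
    """Branch brackets in a pattern do not balance."""


class TooLarge(GlycoCTError):
    """Input exceeds the size guard of an exhaustive operation."""


class UnknownQueryId(GlycoCTError):
    """Catalog query id outside 1..16 / Q1..Q6."""


class NoAttachmentPoint(GlycoCTError):
    """No residue with a free carbon can accept the grafted motif."""


class InvalidBaseURI(GlycoCTError):
    """Base URI for RDF export is not an absolute URI."""
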