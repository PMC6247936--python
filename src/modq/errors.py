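"""Exception and warning hierarchy.

All recoverable data errors derive from :class:`ModqError`; anomalies that
produce a defined result (degenerate module definitions, singleton groups,
approximate set covers) are surfaced as warnings instead.
"""


class ModqError(Exception):
    """Base class for all package errors."""


class DefinitionSyntaxError(ModqError):
    """Raised when a module definition string cannot be tokenized or parsed.

    Carries the 0-based character ``offset`` of the offending position when
    known.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class NamespaceMismatch(ModqError):
    """Gene set and definition use different identifier namespaces."""


class EmptySelection(ModqError):
    """A module filter matched no module."""


class EmptyQuery(ModqError):
    """A query was issued with no genes."""


class MalformedRecord(ModqError):
    """A flat-file record violates the dialect (e.g. missing ENTRY)."""


class MalformedLine(ModqError):
    """A .list line does not have exactly two columns."""


class InsufficientPoints(ModqError):
    """Fewer than two points supplied to a pairwise-distance statistic."""


class InsufficientRows(ModqError):
    """Fewer rows than the statistic requires."""


class UnassignedRow(ModqError):
    """A factor assignment does not cover every row of the matrix."""


class EmptyMatrix(ModqError):
    """A plot or statistic received an empty matrix."""


class RaggedHierarchy(ModqError):
    """Sunburst hierarchy paths have differing depths and padding is off."""


class UnachievableTarget(ModqError):
    """A fixture completeness target is not representable as k/n_blocks."""


class DegenerateDefinitionWarning(UserWarning):
    """Module definition has no countable blocks; completeness defined as 1."""


class SingletonGroupWarning(UserWarning):
    """A factor group with a single member has an undefined spread."""


class ApproximateCoverWarning(UserWarning):
    """The overall completion set was found greedily, not exactly."""


class UnknownGenomeWarning(UserWarning):
    """A mapping references a genome absent from the genome flat file."""


class ParseWarning(UserWarning):
    """Non-fatal flat-file anomaly (empty file, unterminated record)."""
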