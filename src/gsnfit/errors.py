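"""Exception hierarchy.

All package-specific failures derive from :class:`GsnError` so callers can
catch one base class. Structural problems discovered by :func:`validate`
are *returned* as issues, not raised; exceptions are reserved for misuse of
the construction API and for unusable on-disk documents.
"""

from __future__ import annotations


class GsnError(Exception):
    """Base class for all errors raised by gsnfit."""


class InvalidArgumentError(GsnError, ValueError):
    """A function argument violates a precondition (empty statement, bad count...)."""


class NodeNotFoundError(GsnError, KeyError):
    """A uid or label does not resolve to a node in the graph."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class EdgeTypingError(GsnError):
    """An illegal (parent kind, child kind) pairing was requested."""


class GraphValidationError(GsnError):
    """An operation requiring a well-formed graph was given a malformed one.

    Carries the list of :class:`~gsnfit.core.ValidationIssue` that caused
    the rejection.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        codes = ", ".join(sorted({i.code for i in self.issues}))
        super().__init__(f"graph is not well-formed: {codes}")


class DocumentFormatError(GsnError):
    """An on-disk document is not a readable gsn-argument file."""


class DuplicateUidError(DocumentFormatError):
    """A document declares the same node uid more than once."""


class DanglingEdgeError(DocumentFormatError):
    """A document edge references a uid that is not declared."""
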