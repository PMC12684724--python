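"""Exception hierarchy.

Errors are categorized so the CLI can map them to exit diagnostics:
schema (malformed tables), validation (value/invariant violations),
computation (degenerate numerics), io (filesystem).
"""


class IsocontextError(Exception):
    """Base class for all package errors."""

    category = "computation"


class SchemaError(IsocontextError):
    """A table is missing mandatory columns or violates uniqueness."""

    category = "schema"


class ParseError(IsocontextError):
    """A cell or token could not be parsed; carries row/position context."""

    category = "schema"


class ValidationError(IsocontextError):
    """A value violates a domain invariant (range, enum, sum constraint)."""

    category = "validation"


class ConfigurationError(IsocontextError):
    """Parameters or run setup are inconsistent with the data."""

    category = "validation"


class GraphIntegrityError(IsocontextError):
    """A graph edge references a node that does not exist."""

    category = "validation"


class DegenerateSolutionError(IsocontextError):
    """A numerical routine produced an unusable solution (e.g. all-zero)."""

    category = "computation"
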