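"""Exception hierarchy for trivasc.

``TrivascError`` is the base for everything this package raises on bad
input; ``ParseError`` and ``StructureError`` carry file/line context so
CLI users can locate the offending record.
"""


class TrivascError(Exception):
    """Base class for all trivasc errors."""


class ParseError(TrivascError):
    """Malformed text input (wrong column count, non-numeric field ...)."""


class StructureError(TrivascError):
    """Structurally invalid input (dangling parent, duplicate key ...)."""


class ValidationError(TrivascError):
    """Arguments or configuration violating a documented precondition."""


class DegenerateInputError(TrivascError):
    """Input is well-formed but degenerate for the requested computation."""
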