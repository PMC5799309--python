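"""Exception hierarchy.

ValidationError maps to CLI exit code 2, anything else to 1.
"""


class GsaqError(Exception):
    """Base class for all package errors."""


class ValidationError(GsaqError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(GsaqError, ValueError):
    """A file could not be parsed; message names the offending line."""
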