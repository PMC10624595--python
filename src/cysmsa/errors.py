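"""Exception hierarchy.

Everything the package raises on bad user input derives from
:class:`CysmsaError`, so callers (and the CLI) can distinguish validation
failures (exit 1) from genuine bugs.
"""


class CysmsaError(Exception):
    """Base class for all package-level errors."""


class ParseError(CysmsaError):
    """A file or stream could not be parsed."""


class ValidationError(CysmsaError):
    """An in-memory object or argument violates a documented invariant."""
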