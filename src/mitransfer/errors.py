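"""Exception hierarchy for input parsing and validation."""


class MitransferError(Exception):
    """Base class for all package errors."""


class ParseError(MitransferError):
    """A file could not be parsed (malformed structure, bad cell)."""


class SchemaError(MitransferError):
    """A table is missing required columns."""


class ValidationError(MitransferError):
    """Parsed data violates a domain invariant."""
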