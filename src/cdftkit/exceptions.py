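"""Exception hierarchy shared across the toolkit."""


class CdftkitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(CdftkitError):
    """A tabular input is missing a mandatory column or carries a bad header."""


class ValidationError(CdftkitError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(CdftkitError):
    """A text input (log or cube file) could not be parsed."""


class GenerationError(CdftkitError):
    """A synthetic-data request cannot be satisfied (e.g. grid too coarse)."""
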