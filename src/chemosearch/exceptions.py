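"""Exception types shared across the package."""


class ChemosearchError(Exception):
    """Base class for package errors."""


class InvalidParameterError(ChemosearchError, ValueError):
    """A model, landscape, or configuration parameter is out of range."""


class ValidationError(ChemosearchError, ValueError):
    """Input data violate a structural invariant (ordering, sign, length)."""


class FormatError(ChemosearchError, ValueError):
    """A track file does not match the expected delimited-text dialect."""


class InsufficientDataError(ChemosearchError, ValueError):
    """Too few samples for the requested statistic."""
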