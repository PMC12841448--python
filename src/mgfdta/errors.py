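"""Exception hierarchy shared across the package."""


class MGFDTAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MGFDTAError, ValueError):
    """A parameter is outside its admissible range."""


class EmptyInputError(MGFDTAError, ValueError):
    """An operation received an empty corpus, batch or split."""


class ParseError(MGFDTAError, ValueError):
    """An input string (SMILES, table row) could not be parsed."""


class DegenerateInputError(MGFDTAError, ValueError):
    """Input is structurally valid but degenerate (e.g. fully masked)."""


class ConfigurationError(MGFDTAError, ValueError):
    """Inconsistent shapes or configuration values."""


class SchemaError(MGFDTAError, ValueError):
    """A tabular input is missing required columns."""


class LeakageError(MGFDTAError, ValueError):
    """Train/validation/test contamination was detected."""


class UndefinedMetricError(MGFDTAError, ValueError):
    """A metric is undefined for the given inputs (e.g. constant labels)."""
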