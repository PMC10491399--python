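"""Exception hierarchy shared across the pipeline.

Three failure classes map onto the CLI exit codes: format problems in an
input file, validation failures of an otherwise well-formed object, and
configuration errors (impossible parameter combinations).
"""


class ChemoscreenError(Exception):
    """Base class for all package errors."""


class FormatError(ChemoscreenError):
    """An input file does not conform to its expected layout."""


class ValidationError(ChemoscreenError):
    """Parsed data violate an invariant (duplicates, negative counts, ...)."""


class ConfigurationError(ChemoscreenError):
    """Parameters or sample design make the requested operation impossible."""
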