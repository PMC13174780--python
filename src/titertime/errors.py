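"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to exit code 3.
"""


class TiterTimeError(Exception):
    """Base class for all package errors."""


class ConfigError(TiterTimeError):
    """Invalid configuration (bad stage name, infeasible parameter, ...)."""


class DataError(TiterTimeError):
    """Invalid or degenerate data."""


class SchemaError(DataError):
    """A required column or field is missing or malformed."""


class IntegrityError(DataError):
    """Records violate a structural invariant (duplicates, missing replicates)."""
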