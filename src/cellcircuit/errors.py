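"""Exception hierarchy shared across the pipeline.

Config and schema problems are distinguished from data-integrity problems so
the CLI can map them to distinct exit codes (2 vs 3).
"""


class CircuitError(Exception):
    """Base class for all package errors."""


class SchemaError(CircuitError):
    """An input file is missing a required column or field."""


class ParseError(CircuitError):
    """A value in an input file could not be interpreted."""


class IntegrityError(CircuitError):
    """Input content violates an invariant (duplicates, dimension mismatch)."""


class ConfigError(CircuitError):
    """A configuration object is invalid or internally inconsistent."""


class DegenerateInputError(CircuitError):
    """The input admits no meaningful fit (e.g. all rows identical)."""


class ConvergenceError(CircuitError):
    """An optimizer failed to converge; carries diagnostics in args."""


class SeparationError(CircuitError):
    """Perfect separation: the likelihood is unbounded in a coefficient."""
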