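"""Exception hierarchy.

The CLI maps these onto exit codes: config errors -> 2, input format and
validation errors -> 3, numerical failures -> 4.
"""


class NnctError(Exception):
    """Base class for all package errors."""


class FormatError(NnctError):
    """A file could not be parsed into the expected shape or columns."""


class ValidationError(NnctError):
    """Parsed data violates a domain invariant (asymmetry, bad label, ...)."""


class ParameterError(ValidationError):
    """A caller-supplied parameter is outside its admissible range."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but degenerate for the requested operation
    (zero variance, empty network, graph too small to rewire, ...)."""


class NumericalError(NnctError):
    """A numerical procedure failed."""


class ConvergenceError(NumericalError):
    """An iterative or series computation does not converge
    (spectral radius >= 1, endpoint error above tolerance)."""


class SolvabilityError(NumericalError):
    """A linear boundary map is singular: the requested transition is not
    achievable with the chosen control set."""


class ConfigError(NnctError):
    """A run configuration file is malformed or inconsistent."""
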