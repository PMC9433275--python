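"""Exception hierarchy with CLI exit codes.

Exit-code convention: 0 success, 2 configuration error, 3 input error,
4 runtime/training error.
"""


class PPIIError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 4


class ConfigError(PPIIError):
    """Invalid, unknown, or ill-typed configuration."""

    exit_code = 2


class InputError(PPIIError):
    """Unreadable or inconsistent input data."""

    exit_code = 3


class ParseError(InputError):
    """A coordinate or table file could not be parsed."""


class GeometryError(PPIIError):
    """Degenerate geometry (e.g. collinear atoms in a torsion)."""


class TrainingError(PPIIError):
    """Training diverged or could not proceed."""
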