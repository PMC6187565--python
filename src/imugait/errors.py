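"""Exception hierarchy shared across the package."""


class ImuGaitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ImuGaitError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ImuGaitError, ValueError):
    """Input is formally valid but numerically degenerate (zero norm, antipodal pair, ...)."""


class FitError(ImuGaitError, RuntimeError):
    """A least-squares / eigenproblem fit failed or produced a non-ellipsoid."""


class ParseError(ImuGaitError, ValueError):
    """A delimited-text log could not be parsed; message names the offending line."""


class GapError(ImuGaitError, ValueError):
    """Timestamp gaps too large for safe integration; message lists sample indices."""


class ConfigError(ImuGaitError, ValueError):
    """Pipeline configuration is inconsistent or references missing inputs."""
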