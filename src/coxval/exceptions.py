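"""Exception hierarchy.

Exit codes (used by the CLI) distinguish configuration errors (bad model
spec, bad options), data errors (problems in the validation dataset), and
numerical failures (non-convergence, singular information).
"""


class CoxValError(Exception):
    """Base class for all coxval errors."""

    exit_code = 1


class ConfigurationError(CoxValError):
    """Invalid model specification, options, or call sequencing."""

    exit_code = 2


class DataError(CoxValError):
    """Invalid or degenerate data (bad event coding, no events, ...)."""

    exit_code = 3


class ConvergenceError(CoxValError):
    """Numerical failure: monotone likelihood, singular information."""

    exit_code = 4
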