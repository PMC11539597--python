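"""Exception hierarchy shared across the package.

Three families are distinguished so the command line can map them to
distinct exit codes: bad configuration, bad data, and everything else.
"""


class GlycofuseError(Exception):
    """Base class for package errors."""


class ConfigurationError(GlycofuseError, ValueError):
    """A parameter, design or config file is invalid."""


class DataError(GlycofuseError, ValueError):
    """An input matrix/table violates a precondition."""


class ConvergenceError(GlycofuseError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, n_iter: int | None = None, delta: float | None = None):
        super().__init__(message)
        self.n_iter = n_iter
        self.delta = delta
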