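"""Exception hierarchy shared across the package.

Every error raised on bad scientific input derives from :class:`EraError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class EraError(Exception):
    """Base class for all domain errors."""


class InvalidParameterError(EraError, ValueError):
    """A parameter violates its physical or statistical constraints."""


class NoDataError(EraError):
    """An operation that needs at least one observation received none."""


class FitFailureError(EraError):
    """A curve fit did not converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Solver message and the data that produced the failure.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IndeterminateCensoringError(EraError):
    """A nondetect's LOQ lies above the queried threshold, so the
    comparison cannot be resolved from the data."""


class InvalidNetworkError(EraError):
    """A river network is not a forest draining to outlets."""


class ConfigError(EraError):
    """A run configuration failed validation; names the offending field."""
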