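"""Exception hierarchy.

All package errors derive from :class:`BolusFluxError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class BolusFluxError(Exception):
    """Base class for all package errors."""


class InputError(BolusFluxError):
    """Malformed or inconsistent input data (non-monotone times, missing columns...)."""


class DomainError(BolusFluxError, ValueError):
    """Argument outside its mathematical domain (negative ratio, AUC <= 0...)."""


class ConfigurationError(BolusFluxError):
    """A required piece of configuration or data is absent (e.g. no baseline sample)."""


class NoValidTailError(BolusFluxError):
    """Terminal log-linear fit failed: no decaying tail could be identified."""


class MissingTimesError(InputError):
    """A sampling schedule requests times absent from the measured curve."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"schedule requests {len(self.missing)} time point(s) absent from the "
            f"curve: {self.missing[:10]}{'...' if len(self.missing) > 10 else ''}"
        )
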