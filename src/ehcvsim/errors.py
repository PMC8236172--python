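"""Exception types raised by the simulation."""


class EhcvError(Exception):
    """Base class for all package errors."""


class ValidationError(EhcvError, ValueError):
    """An input violated a documented invariant."""


class IntegrationInstabilityError(EhcvError):
    """An Euler step drove a stock negative (time step too large)."""


class UndefinedRatioError(EhcvError, ZeroDivisionError):
    """Public-to-private ratio requested with zero private visits."""


class CalibrationFailureError(EhcvError):
    """The calibration objective was non-finite at every start point."""


class FixtureIntegrityError(EhcvError):
    """A packaged fixture failed its self-check on load."""
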