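"""Exception hierarchy shared across the package."""


class CybedError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CybedError, ValueError):
    """A model parameter violates its domain (e.g. negative abundance, d outside (0, 1])."""


class CalibrationError(CybedError, ValueError):
    """Bedding calibration is infeasible (fractions sum to >= 1)."""


class ConfigurationError(CybedError, ValueError):
    """A configuration file or registry lookup is malformed or missing."""


class IntegrationError(CybedError, RuntimeError):
    """The ODE integrator failed to meet its tolerance.

    Carries the time at which integration failed, when known.
    """

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class DegenerateTableError(CybedError, ValueError):
    """A contingency table has an empty margin, making the statistic undefined."""


class UndefinedStatisticError(CybedError, ZeroDivisionError):
    """A denominator required by a statistic is zero (e.g. zero cage openings)."""
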