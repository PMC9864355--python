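"""Exception hierarchy.

All model errors derive from :class:`DgDisError` so callers can catch one
base class; validation errors additionally derive from :class:`ValueError`
to behave naturally in numeric code.
"""


class DgDisError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DgDisError, ValueError):
    """A model parameter violates its constraints (e.g. non-positive LoA)."""


class InvalidInputError(DgDisError, ValueError):
    """A patient input violates its constraints (e.g. non-positive CO)."""


class ModelDomainError(DgDisError, ValueError):
    """The input lies outside the model's domain of validity.

    Raised when the observed CO_TD falls outside the physiological interval
    [a, b] (the conditioning presumes a physiological observed CO), or when
    a disagreement probability is requested for a patient whose pressures
    do not meet the mPAP/PAWP entry criteria.
    """


class WrongDirectionError(DgDisError, ValueError):
    """A direction-specific probability was requested for the other branch."""


class DegenerateConditionError(DgDisError, ArithmeticError):
    """The conditioning event B has (numerically) zero probability."""


class InsufficientDataError(DgDisError, ValueError):
    """Too few paired measurements for the requested statistic."""


class GeneratorStalledError(DgDisError, RuntimeError):
    """Rejection sampling accepts too few proposals to be practical."""
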