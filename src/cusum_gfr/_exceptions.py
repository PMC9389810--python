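"""Exception types shared across the package."""


class CusumGfrError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CusumGfrError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(CusumGfrError, ValueError):
    """A requested value lies outside the attainable range of a map."""


class InsufficientDataError(CusumGfrError, ValueError):
    """Not enough observations to compute the requested quantity."""


class UndefinedMetricError(CusumGfrError, ValueError):
    """A performance metric has an empty denominator class."""


class DataError(CusumGfrError, ValueError):
    """Input records are internally inconsistent."""


class SimConfigError(CusumGfrError, ValueError):
    """A simulation configuration cannot produce valid patients."""
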