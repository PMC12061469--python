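"""Exception hierarchy shared by all pipeline stages."""


class CallVarError(Exception):
    """Base class for all callvar errors."""


class InvalidParameterError(CallVarError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CallVarError, ValueError):
    """Not enough observations to compute the requested statistic."""


class UndefinedStatisticError(CallVarError, ValueError):
    """The statistic is mathematically undefined for this input
    (zero mean, zero variance, constant distance matrix, ...)."""


class MeasurementError(CallVarError, ValueError):
    """A call could not be measured (no energy, no pulses, ...)."""
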