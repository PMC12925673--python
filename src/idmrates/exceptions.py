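"""Exception hierarchy for idmrates."""


class IdmError(Exception):
    """Base class for all idmrates errors."""


class InvalidParameterError(IdmError, ValueError):
    """A rate-function or model parameter violates its constraints."""


class DomainError(IdmError, ValueError):
    """A state variable (prevalence, rate, ratio) is outside its domain."""


class ConfigError(IdmError, ValueError):
    """A generator or analysis configuration is invalid."""


class EmptyDataError(IdmError, ValueError):
    """No usable records remain after filtering."""


class FitError(IdmError, RuntimeError):
    """A regression fit failed to converge or produced invalid coefficients."""


class EstimationError(IdmError, RuntimeError):
    """The least-squares rate estimation failed across all starts."""


class EnsembleError(IdmError, RuntimeError):
    """Too many bootstrap replicates failed to converge."""
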