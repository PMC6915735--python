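"""Exception hierarchy shared by all pipeline stages."""


class AridWheatError(Exception):
    """Base class for all package errors."""


class ParameterError(AridWheatError, ValueError):
    """A parameter value is outside its physical or logical domain."""


class DataError(AridWheatError, ValueError):
    """An input series violates its contract (gaps, tmin > tmax, bad window...)."""


class ConfigurationError(AridWheatError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class SimulationError(AridWheatError, RuntimeError):
    """A simulation could not be completed (e.g. maturity never reached)."""
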