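"""Exception types shared across the package."""


class PvaeError(Exception):
    """Base class for package errors."""


class InvalidRateError(PvaeError, ValueError):
    """A Poisson rate was nonpositive, NaN, or infinite."""


class ContractError(PvaeError, ValueError):
    """An argument violated a documented shape/value contract."""


class ConfigError(PvaeError, ValueError):
    """An experiment or model configuration is invalid."""


class DivergenceError(PvaeError, RuntimeError):
    """Iterative dynamics produced non-finite values or a growing objective."""


class StepSizeError(DivergenceError):
    """ISTA objective increased beyond tolerance; step size too large."""
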