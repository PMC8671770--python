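"""Exception types shared across the pipeline."""


class EdmoodError(Exception):
    """Base class for all package errors."""


class ScoringError(EdmoodError, ValueError):
    """An item response is missing or outside its permitted range."""


class InsufficientSampleError(EdmoodError, ValueError):
    """Too few respondents for the requested statistic."""


class UndefinedStatisticError(EdmoodError, ValueError):
    """The statistic is undefined for this input (e.g. zero variance)."""


class ConfigError(EdmoodError, ValueError):
    """A generator or pipeline configuration value is invalid."""
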