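"""Exception types raised across the model pipeline."""


class QuitceaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuitceaError):
    """A parameter, ratio or config field is missing or out of range."""


class DataConsistencyError(QuitceaError):
    """Input tables violate a required relationship (e.g. negative residual)."""


class ModelConsistencyError(QuitceaError):
    """A transition row over-allocates probability mass."""
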