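"""Exception hierarchy shared across the package."""


class ElastrackError(Exception):
    """Base class for all package errors."""


class ConfigError(ElastrackError):
    """Missing or inconsistent configuration / metadata."""


class InputDataError(ElastrackError):
    """Malformed or degenerate input data."""


class ParameterError(ElastrackError):
    """Invalid algorithm parameter."""


class AssemblyError(ElastrackError):
    """Non-finite entries while assembling the linear system."""


class SolverError(ElastrackError):
    """The assembled system could not be solved."""


class DivergenceError(ElastrackError):
    """The outer iteration diverged (cost increased persistently)."""


class MetricError(ElastrackError):
    """An image-quality metric is undefined for the given input."""
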