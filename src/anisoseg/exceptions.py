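"""Exception hierarchy shared across the package."""


class AnisosegError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AnisosegError, ValueError):
    """A model or SSM parameter violates its domain (e.g. non-positive step size)."""


class DimensionError(AnisosegError, ValueError):
    """Array shapes are inconsistent with each other or with a configuration."""


class ConfigurationError(AnisosegError, ValueError):
    """A configuration value is unknown or internally inconsistent."""


class UnsupportedModeError(AnisosegError, ValueError):
    """An operation was requested in a mode it does not support."""


class NumericError(AnisosegError, ArithmeticError):
    """A non-finite value appeared where finite arithmetic was required."""


class GenerationError(AnisosegError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class UndefinedMetricError(AnisosegError, ValueError):
    """A metric is undefined for the given input (e.g. empty ground truth)."""
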