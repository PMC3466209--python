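"""Exception types shared across the package."""


class FilmSemError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FilmSemError, ValueError):
    """An input lies outside the physical or numerical domain of an operation."""


class MeasurementError(FilmSemError, RuntimeError):
    """A measurement (e.g. an edge-resolution estimate) could not be completed.

    Carries a human-readable diagnostic describing what was looked for and
    what was found instead.
    """


class ConfigError(FilmSemError, ValueError):
    """A configuration file violated the documented schema."""
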