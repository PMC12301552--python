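"""Exception hierarchy shared across the package."""


class RefIntervalsError(Exception):
    """Base class for all package errors."""


class SchemaError(RefIntervalsError):
    """Input table violates the expected column schema."""


class IntegrityError(RefIntervalsError):
    """Input table content is inconsistent (duplicates, mixed units)."""


class ConfigError(RefIntervalsError):
    """Invalid policy or simulation configuration."""


class SeriesLookupError(RefIntervalsError, KeyError):
    """Requested measurand or partition does not exist in the table."""


class DegenerateDataError(RefIntervalsError, ValueError):
    """Input too short, constant, or otherwise unusable for the operation."""


class DomainError(RefIntervalsError, ValueError):
    """Values outside the mathematical domain of the operation."""
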