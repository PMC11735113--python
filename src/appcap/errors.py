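"""Exception hierarchy for the capacity model."""


class ModelError(Exception):
    """Base class for all model-specific errors."""


class ConfigError(ModelError):
    """Scenario file could not be parsed or fails validation."""


class SchemaError(ModelError):
    """An input table is missing a required column or key."""


class BoundaryMismatchError(ModelError):
    """A minimum age does not align with an age-band boundary."""


class InfeasibleWeekError(ModelError):
    """Fixed activity blocks exceed the available weekly hours."""
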