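"""Exception hierarchy for the brainage package."""


class BrainAgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BrainAgeError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataValidationError(BrainAgeError, ValueError):
    """An input table violates a structural contract (missing column,
    duplicate key, non-finite value, unmapped feature, ...)."""


class ModelError(BrainAgeError, ValueError):
    """A model cannot be fitted or applied (too few rows for a sex,
    missing feature at prediction time, unknown sex code, ...)."""


class StatisticsError(BrainAgeError, ValueError):
    """A statistical operation is undefined on the given input
    (constant matrix for an ICC, zero pooled SD for an effect size, ...)."""
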