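"""Exception hierarchy for the pipeline."""


class IegDecodeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(IegDecodeError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(IegDecodeError):
    """An input table is missing required columns or has malformed values."""


class MissingReferenceError(IegDecodeError):
    """A sample lacks the reference genes needed for normalization."""


class NormalizationError(IegDecodeError):
    """A control group required for fold-induction normalization is empty."""


class FeatureError(IegDecodeError):
    """A feature matrix is incomplete or inconsistent with the request."""
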