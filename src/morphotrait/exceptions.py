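"""Exception hierarchy shared across the pipeline stages."""


class MorphotraitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MorphotraitError):
    """Invalid cohort / pipeline configuration (bad proportions, ranges...)."""


class SchemaError(MorphotraitError):
    """A table or file violates the expected schema (missing column/field)."""


class DimensionError(MorphotraitError):
    """Shape, label or mask mismatch between inputs."""


class DesignMatrixError(MorphotraitError):
    """Rank-deficient or otherwise unusable covariate design."""


class DegenerateDataError(MorphotraitError):
    """Zero-variance or otherwise degenerate data where a statistic is undefined."""


class SampleLeakageError(MorphotraitError):
    """Exploration subjects found in a validation-only stage."""
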