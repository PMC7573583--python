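"""Exception hierarchy shared across the package."""


class ConnsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ConnsigError):
    """Invalid parameter combination (counts, thresholds, weights)."""


class SchemaError(ConnsigError):
    """A table is missing a required column or has the wrong layout."""


class IntegrityError(ConnsigError):
    """Duplicate identifiers or inconsistent cross-references in inputs."""


class DesignMatrixError(ConnsigError):
    """Rank-deficient or under-determined regression design."""


class DegenerateDataError(ConnsigError):
    """Zero-variance / zero-IQR signal where a scale is required."""


class SampleSizeError(ConnsigError):
    """Too few subjects, donors or observations for the requested test."""


class LeakageError(ConnsigError):
    """Subject overlap between a signature's source cohort and its target."""
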