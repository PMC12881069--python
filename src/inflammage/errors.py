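"""Exception hierarchy shared across the package."""


class InflammageError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(InflammageError):
    """An input table or value violates a documented contract."""


class SchemaError(InflammageError):
    """Column names / parameter names do not line up between inputs."""


class ScoringError(InflammageError):
    """A score cannot be computed for the given inputs."""


class InsufficientDataError(InflammageError):
    """Too few observations for the requested statistic."""


class CollinearityError(InflammageError):
    """A regression design matrix is rank deficient."""
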