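"""Exception hierarchy shared across the package."""


class AllRiskError(Exception):
    """Base class for package-specific errors."""


class SchemaError(AllRiskError):
    """A cohort file violates the documented column schema or enum codes."""


class ConfigError(AllRiskError):
    """An invalid configuration value (probability vectors, thresholds, ...)."""


class MissingCovariateError(AllRiskError):
    """A covariate required by the active coefficient set is absent.

    Carries the offending field name in ``field``.
    """

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing required covariate: {field!r}")


class CohortExclusionError(AllRiskError):
    """The record does not belong to the analysis cohort for this endpoint
    (e.g. induction death when deriving relapse-free survival)."""


class UnfitError(AllRiskError):
    """A model could not be fit (no events, or the optimizer failed)."""


class SingularityError(AllRiskError):
    """The design matrix is singular (constant or collinear column)."""


class UndefinedResultError(AllRiskError):
    """A statistic is undefined for this input (e.g. no usable pairs)."""


class UnclassifiedError(AllRiskError):
    """No clinical rule matched and no default label was configured, or a
    rule referenced a field missing from the record."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message)
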