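"""Exception hierarchy shared across the package."""


class OsteophenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OsteophenError):
    """Invalid simulation or pipeline configuration; message names the field."""


class ValidationError(OsteophenError):
    """Invalid domain values (negative areas, Fy > Fu, negative glucose ...)."""


class DesignError(OsteophenError):
    """ANOVA design cannot be estimated (single strain, single sex ...)."""


class SchemaError(OsteophenError):
    """Cohort CSV is missing a required column; message names the column."""


class IntegrityError(OsteophenError):
    """Duplicate animal ids or inconsistent table contents."""


class MappingError(OsteophenError):
    """A row refers to a strain unknown to a fitted model."""


class DependencyError(OsteophenError):
    """An operation was called without its prerequisite artifact."""


class ContrastError(OsteophenError):
    """A requested post hoc contrast refers to an absent group."""


class GeometryError(OsteophenError):
    """Non-positive beam section properties."""


class CurveTooShortError(OsteophenError):
    """Too few samples before the ultimate force to fit a stiffness window."""


class DegenerateCurveError(OsteophenError):
    """Curve carries no usable elastic slope (flat or non-positive)."""


class BoundsError(OsteophenError):
    """A band window lies outside the recorded spectral range."""


class FitError(OsteophenError):
    """A least-squares fit could not be performed (order too high, no points)."""
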