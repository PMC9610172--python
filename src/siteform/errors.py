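"""Exception hierarchy shared across the package."""


class SiteFormError(Exception):
    """Base class for all package errors."""


class FormatError(SiteFormError):
    """Input table does not match the expected layout (e.g. missing column)."""


class ValidationError(SiteFormError):
    """Input data violates an integrity constraint (e.g. duplicate keys)."""


class DomainError(SiteFormError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class SingularSiteError(DomainError):
    """The GADA site variable is undefined (1 + beta1/D1 = 0)."""


class InsufficientDataError(SiteFormError):
    """Too few observations to fit or summarize."""


class UnidentifiableError(SiteFormError):
    """The design carries no information about the parameter(s)."""


class FittingError(SiteFormError):
    """Nonlinear optimisation failed to converge after multi-start."""


class DegreesOfFreedomError(SiteFormError):
    """n <= p: goodness-of-fit statistics undefined."""


class CoefficientError(SiteFormError):
    """A volume-coefficient set produced an invalid (negative) volume."""


class ZeroVarianceError(SiteFormError):
    """A correlation is undefined because one variable is constant."""


class NoDominantsError(SiteFormError):
    """A plot has no re-measured live trees eligible as dominants."""


class MissingHeightError(SiteFormError):
    """An operation requiring measured heights met a tree without one."""


class ConfigError(SiteFormError):
    """Synthetic-data or run configuration is infeasible or inconsistent."""


class JoinError(SiteFormError):
    """Tables could not be aligned on their shared identifier."""
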