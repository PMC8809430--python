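"""Exception hierarchy shared across the package."""


class VultureSurveyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VultureSurveyError):
    """A config file, column map, or parameter block is malformed."""


class ValidationError(VultureSurveyError):
    """Input data violate a structural invariant (bad count, shape, duplicate key...)."""


class DegenerateCovariateError(ValidationError):
    """All covariate values are equal; scaling to unit SD is undefined."""


class UndefinedStatisticError(VultureSurveyError):
    """A statistic's defining formula divides by zero for this input."""
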