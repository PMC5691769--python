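"""Exception hierarchy shared across the package."""


class CohortError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CohortError):
    """A configuration object violates its invariants."""


class ValidationError(CohortError):
    """An input value is outside its documented domain."""


class CohortParseError(CohortError):
    """A cohort file could not be parsed against the schema."""


class MatchingError(CohortError):
    """A matching procedure could not satisfy its balance contract."""


class SeparationError(CohortError):
    """A logistic fit failed due to (quasi-)complete separation."""
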