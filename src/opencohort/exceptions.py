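"""Exception hierarchy for opencohort."""


class OpenCohortError(Exception):
    """Base class for all opencohort errors."""


class InvalidDesignError(OpenCohortError, ValueError):
    """Raised for malformed trial design schematics."""


class SingularDesignError(OpenCohortError):
    """Raised when a design carries no information about the treatment effect
    (e.g. no treatment contrast, so the design-effect denominator vanishes)."""


class InvalidSchemeError(OpenCohortError, ValueError):
    """Raised for malformed sampling schemes or churn values outside [0, 1]."""


class SingularCovarianceError(OpenCohortError):
    """Raised when a covariance matrix of cluster-period means is not
    (numerically) invertible."""


class MembershipConstructionError(OpenCohortError):
    """Raised when no integer membership matrix consistent with a sampling
    scheme can be constructed (possible only for custom churn tables)."""
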