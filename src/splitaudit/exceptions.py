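"""Exception hierarchy for splitaudit.

Every error raised by the library derives from :class:`SplitAuditError`, so
callers can catch one base class at pipeline boundaries while tests can assert
the specific failure mode.
"""


class SplitAuditError(Exception):
    """Base class for all splitaudit errors."""


class ConfigurationError(SplitAuditError):
    """A parameter object is internally inconsistent or infeasible."""


class SchemaError(SplitAuditError):
    """A cohort file or table violates the documented schema."""


class DegenerateFeatureError(SplitAuditError):
    """A feature is constant within a vendor stratum on the fit set."""


class MissingStratumError(SplitAuditError):
    """A vendor stratum appears at apply time that was absent at fit time."""


class InfeasibleSplitError(SplitAuditError):
    """A requested stratified allocation would empty a class in one arm."""


class DegenerateLabelsError(SplitAuditError):
    """A label vector contains a single class where two are required."""


class UndefinedTestError(SplitAuditError):
    """A statistical test is undefined for the given data (e.g. zero variance)."""


class PairingError(SplitAuditError):
    """Two result lists that must share split ids do not."""
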