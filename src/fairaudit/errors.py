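"""Exception hierarchy.

Undefined fairness metrics raise structured errors instead of returning NaN so
the audit harness can count and report skipped iterations.
"""


class FairauditError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FairauditError, ValueError):
    """An invalid configuration field; the message names the field."""


class SchemaError(FairauditError, ValueError):
    """A cohort table violates the expected schema."""


class PreprocessingError(FairauditError, ValueError):
    """Imputation / scaling / PCA cannot be fitted or applied."""


class SmoteError(FairauditError, ValueError):
    """SMOTE preconditions violated (single class, minority too small)."""


class UndefinedMetricError(FairauditError, ValueError):
    """A fairness metric's defining denominator is zero or a group is empty."""


class DegenerateSampleError(FairauditError, ValueError):
    """A statistical test received samples it cannot handle."""


class RepairError(FairauditError, ValueError):
    """Disparate-impact-remover fitting or application failed."""


class HarnessError(FairauditError, RuntimeError):
    """The audit harness could not complete (e.g. too many skipped iterations)."""


class ReportError(FairauditError, ValueError):
    """Report rendering received inconsistent inputs."""
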