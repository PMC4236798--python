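"""Exception hierarchy for the pipeline.

The CLI maps ConfigurationError to exit code 2 and DataError to exit
code 3; everything else is a bug.
"""


class EdriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EdriskError):
    """Invalid simulation / screening / selection / pipeline configuration."""


class DataError(EdriskError):
    """Input data violates the cohort-table contract (schema, values, splits)."""


class DegenerateDesignError(DataError):
    """Constant outcome or constant covariate: the logistic MLE is undefined."""


class SeparationError(DataError):
    """Perfect (quasi-)separation: logistic coefficients diverge."""


class UndefinedOddsRatioError(DataError):
    """All four cells of a 2x2 table are zero; no odds ratio exists."""
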