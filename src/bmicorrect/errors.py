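"""Exception hierarchy shared across the package.

Validation problems (bad values, missing covariates, malformed files) are
distinct from numerical failures (singular designs, undefined metrics) so
that callers -- in particular the command line interface -- can map them to
different exit codes.
"""


class BmiCorrectError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BmiCorrectError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class RangeError(BmiCorrectError, ValueError):
    """A query falls outside the range covered by a reference table."""


class MissingDataError(BmiCorrectError, ValueError):
    """A record lacks a covariate required by the requested model."""


class UnitError(BmiCorrectError, ValueError):
    """Incompatible unit systems were mixed."""


class SchemaError(BmiCorrectError, ValueError):
    """A tabular input does not conform to the declared schema."""


class DataError(BmiCorrectError, ValueError):
    """A dataset is unusable for the requested fit (e.g. empty, n <= p)."""


class SingularDesignError(DataError):
    """The design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UndefinedMetricError(BmiCorrectError, ValueError):
    """A diagnostic metric has an empty denominator."""
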