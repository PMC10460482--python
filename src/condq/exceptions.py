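"""Exception types raised across the package."""


class CondqError(Exception):
    """Base class for all condq errors."""


class InvalidParameterError(CondqError, ValueError):
    """A function argument is outside its documented domain."""


class DataError(CondqError, ValueError):
    """An input table violates the test-table contract (bad p-value, missing
    column, duplicate gene identifier, non-finite covariate, ...)."""


class UndefinedMetricError(CondqError, ValueError):
    """A metric is requested on inputs for which it is mathematically
    undefined (e.g. ROC AUC with a single truth class)."""
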