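"""Exception hierarchy shared across the package."""


class QGardenError(Exception):
    """Base class for package errors."""


class InvalidDesignError(QGardenError):
    """A simulation design request is structurally impossible."""


class DegenerateDesignError(QGardenError):
    """Too few grouping levels (or a rank-deficient design) for a model fit."""


class ConvergenceError(QGardenError):
    """An optimizer failed and no usable fit could be produced."""


class UndefinedStatisticError(QGardenError):
    """A derived statistic has a zero denominator or is otherwise undefined."""


class ValidationError(QGardenError):
    """A dataset violates a structural invariant (nesting, duplicates, ...)."""


class UnreliableResultError(QGardenError):
    """Too many resampling refits failed for the result to be trusted."""
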