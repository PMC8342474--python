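"""Exception hierarchy.

The CLI maps :class:`InvalidArgumentError` to exit code 2 (validation)
and the numerical failures to exit code 3.
"""


class SpholoError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SpholoError, ValueError):
    """A precondition on an argument was violated."""


class DegenerateFitError(SpholoError, RuntimeError):
    """A least-squares design matrix is singular (e.g. zero beat frequency)."""


class UndefinedMetricError(SpholoError, ArithmeticError):
    """A metric is undefined for the given inputs (e.g. zero background std)."""
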