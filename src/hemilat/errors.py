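"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`HemilatError`,
so callers can catch one base class at pipeline boundaries while tests can
assert on the specific failure mode.
"""


class HemilatError(Exception):
    """Base class for all errors raised by hemilat."""


class FormatError(HemilatError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class IntegrityError(HemilatError):
    """Data violates a structural invariant (broken homotopic bijection, duplicate ids)."""


class ShapeError(HemilatError):
    """Array dimensions disagree with the atlas or with each other."""


class DegenerateSignalError(HemilatError):
    """A time series or sample has zero variance where variance is required."""


class NumericError(HemilatError):
    """A numeric precondition failed (e.g. covariance not positive semidefinite)."""


class CollinearityError(HemilatError):
    """A design matrix is rank deficient."""


class UndefinedStatisticError(HemilatError):
    """The requested statistic is undefined for this input (zero-norm vector, constant map)."""
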