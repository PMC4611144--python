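"""Exception hierarchy.

All package-specific errors derive from :class:`LfpcaError` so callers can
catch them as a family; each also derives from ``ValueError`` to behave
sensibly in generic code.
"""


class LfpcaError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(LfpcaError, ValueError):
    """Array or volume shapes are inconsistent."""


class DesignError(LfpcaError, ValueError):
    """Subject/visit/time design is invalid (e.g. a single-visit subject)."""


class DataError(LfpcaError, ValueError):
    """Data values are invalid (e.g. NaN inside the analysis mask)."""


class DegenerateDataError(LfpcaError, ValueError):
    """Input carries no usable signal (e.g. an all-zero stack)."""


class SingularDesignError(LfpcaError, ValueError):
    """The moment design is singular or too ill-conditioned to invert."""


class ValidationError(LfpcaError, ValueError):
    """Supplied parameters or components fail their validity checks."""
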