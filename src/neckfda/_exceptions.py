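"""Exception hierarchy.

Every error raised by the package derives from :class:`NeckFDAError` so
callers can catch domain failures without masking programming errors.
"""


class NeckFDAError(Exception):
    """Base class for all package errors."""


class InvalidBasisError(NeckFDAError, ValueError):
    """Basis construction violated a structural rule (e.g. even size)."""


class DomainMismatchError(NeckFDAError, ValueError):
    """Two functional objects live on incompatible domains (periods)."""


class UnsupportedDerivativeError(NeckFDAError, ValueError):
    """Requested derivative order is not implemented."""


class UnderdeterminedFitError(NeckFDAError, ValueError):
    """Fewer samples (or observations) than free coefficients."""


class InsufficientCyclesError(NeckFDAError, ValueError):
    """A continuous record does not contain enough detectable cycles."""

    def __init__(self, n_detected: int, n_required: int = 3):
        self.n_detected = n_detected
        self.n_required = n_required
        super().__init__(
            f"detected {n_detected} cycles; at least {n_required} are required"
        )


class DegenerateCycleError(NeckFDAError, ValueError):
    """A cycle has zero (or negative) duration."""


class GridMismatchError(NeckFDAError, ValueError):
    """Curves expected on a common grid have different grids."""


class IncompleteDataError(NeckFDAError, ValueError):
    """An observation is missing from one of the model terms."""


class CollinearityError(NeckFDAError, ValueError):
    """Design matrix is (numerically) rank deficient."""


class NotNestedError(NeckFDAError, ValueError):
    """The two models of a nested F test are not nested."""


class ConformanceError(NeckFDAError, ValueError):
    """New data do not conform to a fitted model's specification."""


class FormulaError(NeckFDAError, ValueError):
    """A model formula string could not be parsed."""


class SchemaError(NeckFDAError, ValueError):
    """An input table is missing required columns or is malformed."""
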