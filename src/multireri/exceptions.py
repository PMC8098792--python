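"""Exception and warning hierarchy.

All validation failures raise a subclass of :class:`MultiReriError` so that
callers (and the CLI) can distinguish user-input problems from genuine bugs.
"""


class MultiReriError(Exception):
    """Base class for all errors raised by this package."""


class GridError(MultiReriError):
    """Problems constructing or using a relative-risk grid."""


class IncompleteGridError(GridError):
    """A 2^n grid is missing at least one exposure pattern."""


class InvalidRiskError(GridError):
    """A relative risk is non-positive, non-finite, or the reference is not 1."""


class NamingError(GridError):
    """Duplicate or otherwise invalid factor names."""


class PatternLookupError(GridError, KeyError):
    """A pattern does not belong to the grid it was used with."""


class DimensionalityError(MultiReriError):
    """A measure was requested on a grid with an unsupported factor count."""


class SpecificationError(MultiReriError):
    """An interaction-measure specification is malformed (overlapping or
    incomplete subset/conditioning assignments, unknown kind, ...)."""


class MeasureKindError(SpecificationError):
    """An operation was applied to an incompatible measure kind."""


class IncompleteModelError(MultiReriError):
    """A coefficient set does not contain every one of the 2^n - 1 exposure
    terms required by the saturated parameterization."""


class MissingVarianceError(MultiReriError):
    """A variance-requiring operation was called without a covariance matrix."""


class NumericalVarianceError(MultiReriError):
    """The delta-method quadratic form g'Vg came out negative."""


class UnidentifiableCellError(MultiReriError):
    """An exposure pattern has no observations, so its relative risk (and
    therefore every interaction measure) is not estimable."""

    def __init__(self, pattern: str, message: str | None = None):
        self.pattern = pattern
        super().__init__(
            message
            or f"exposure pattern '{pattern}' has no observations; "
            "all 2^n cells must be populated for a saturated fit"
        )


class FitError(MultiReriError):
    """Model fitting failed (separation, non-convergence, ...)."""


class InvalidTableError(MultiReriError):
    """A contingency table violates its invariants."""


class ConfigurationError(MultiReriError):
    """A simulation scenario is internally inconsistent."""


class ScenarioInfeasibleError(MultiReriError):
    """Too many simulation replicates were dropped to report results."""


class ProtectiveFactorError(MultiReriError):
    """RERI computation was requested on a grid with protective factors and
    no explicit override; recode the factors first (see multireri.recode)."""


class MultiReriWarning(UserWarning):
    """Base class for warnings emitted by this package."""


class InfiniteVarianceWarning(MultiReriWarning):
    """A contingency cell with zero cases makes a log-RR variance infinite."""


class MixedOrientationWarning(MultiReriWarning):
    """Reorienting factors left some single-factor RR below 1."""


class ProtectiveFactorWarning(MultiReriWarning):
    """A factor looks protective; additive-interaction measures computed on
    it without recoding are not interpretable."""


class RareDiseaseWarning(MultiReriWarning):
    """Odds ratios approximate relative risks only for rare outcomes."""
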