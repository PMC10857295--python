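"""Exception hierarchy shared across the package."""


class NMCouplingError(Exception):
    """Base class for all package-specific errors."""


class DegenerateMapError(NMCouplingError):
    """A spatial map with zero variance: the SD threshold is undefined."""


class SizingError(NMCouplingError):
    """A requested node size cannot be implanted in a map of the given shape."""


class StructuralError(NMCouplingError):
    """A table is missing a required (subject, component) entry."""


class EmptyGraphError(NMCouplingError):
    """Proportional thresholding retained zero edges."""


class UndefinedCorrelationError(NMCouplingError):
    """Pearson correlation requested on a constant (zero-variance) vector."""


class AlignmentError(NMCouplingError):
    """Subject or component labels disagree between tables."""


class CovarianceError(NMCouplingError):
    """A target covariance could not be made positive definite."""
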