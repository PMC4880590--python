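"""Exception hierarchy for the leafspad pipeline.

All errors derive from :class:`LeafSpadError` so callers (and the CLI) can
catch pipeline failures uniformly while still distinguishing the stage.
"""


class LeafSpadError(Exception):
    """Base class for all leafspad errors."""


class InvalidParameterError(LeafSpadError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(LeafSpadError, ValueError):
    """Input data violate a documented contract (shape, sign, emptiness)."""


class DomainError(LeafSpadError, ValueError):
    """A coordinate lies outside the domain of the object it is applied to."""


class GeometryError(LeafSpadError, ValueError):
    """The requested geometry does not fit the raster canvas."""


class DegenerateStandardsError(LeafSpadError, ValueError):
    """White reflectance standard is not brighter than the black one."""


class EmptySegmentationError(LeafSpadError, ValueError):
    """No leaf-like connected component found in the scan."""


class DegenerateShapeError(LeafSpadError, ValueError):
    """Mask too thin/short to support a width profile."""


class EmptyPartError(LeafSpadError, ValueError):
    """A leaf part has no pixels left after vein/margin exclusion."""


class SingularDesignError(LeafSpadError, ValueError):
    """Regression design matrix is rank deficient (e.g. constant regressor)."""


class InvalidProfileError(LeafSpadError, ValueError):
    """Chlorophyll profile coefficients are unusable (all zero, non-finite)."""


class NoCandidateError(LeafSpadError, ValueError):
    """Position selection was asked to choose among zero candidates."""
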