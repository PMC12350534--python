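"""Exception hierarchy.

Every error raised by this package derives from :class:`DepthRegError`, so
callers can catch a single base class at pipeline boundaries.
"""


class DepthRegError(Exception):
    """Base class for all depthreg errors."""


class InvalidTransformError(DepthRegError):
    """A matrix does not satisfy the rigid-transform invariants."""


class DataError(DepthRegError):
    """Input data is malformed (non-finite coordinates, missing fields)."""


class DegenerateConfigurationError(DepthRegError):
    """A geometric fit has too few or collinear/coplanar points."""


class AmbiguousMeanError(DepthRegError):
    """Rotation averaging over a near-antipodal set has no single branch."""


class ProjectionDomainError(DepthRegError):
    """A point lies behind the camera (z <= 0) and cannot be projected."""


class IllConditionedError(DepthRegError):
    """Calibration problem is ill-conditioned; carries a diagnostic."""


class PoseEstimationError(DepthRegError):
    """Board-pose estimation failed to produce a valid pose."""


class UnderdeterminedError(DepthRegError):
    """Too few captures to constrain the co-registration problem."""


class ConvergenceError(DepthRegError):
    """An iterative solver exhausted its iteration budget.

    Carries ``last_objective`` when available.
    """

    def __init__(self, message, last_objective=None):
        super().__init__(message)
        self.last_objective = last_objective


class VisibilityError(DepthRegError):
    """No surface point is visible from the requested camera placement."""


class PlacementError(DepthRegError):
    """The simulator failed to place the board inside the frustum."""


class InitializationFailureError(DepthRegError):
    """RANSAC global initialization found no transform with enough inliers."""


class DivergenceError(DepthRegError):
    """ICP rejected every correspondence in an iteration.

    Carries ``iteration``.
    """

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


class NoOverlapError(DepthRegError):
    """No source point lies within the distance tolerance of the target."""


class EmptyRoiError(DepthRegError):
    """Cropping to a region of interest produced an empty cloud."""


class FormatError(DepthRegError):
    """A file does not conform to its declared format."""


class ConfigError(DepthRegError):
    """A configuration file or value is invalid."""
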