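"""Exception hierarchy shared by all pipeline stages."""


class PlantCloudError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PlantCloudError, ValueError):
    """Input violates a precondition (wrong shape, too few points, missing normals...)."""


class InvalidTransformError(InvalidInputError):
    """Rotation matrix is not a proper orthonormal rotation."""


class InvalidParameterError(PlantCloudError, ValueError):
    """A filter or optimizer parameter is out of its valid range."""


class DegenerateGeometryError(PlantCloudError):
    """Geometry is degenerate (coplanar/collinear points, zero-area triangle...)."""


class ZeroCovarianceError(DegenerateGeometryError):
    """A normal-estimation neighborhood has zero covariance (all points identical)."""


class EmptyResultError(PlantCloudError):
    """An operation exhausted its input before converging."""


class UndefinedMetricError(PlantCloudError):
    """A metric is undefined for the given input (e.g. empty cloud)."""


class RegistrationError(PlantCloudError):
    """ICP failed (degenerate correspondence set)."""


class MissingInitializerError(RegistrationError):
    """Rough registration has neither a turntable prior nor a pluggable backend."""


class DegenerateBisectorError(DegenerateGeometryError):
    """Median plane of two patches is undefined (anti-parallel normals)."""


class DegenerateProjectionError(DegenerateGeometryError):
    """Projection onto a plane would collapse a triangle below the area floor."""


class EmptyFrameError(PlantCloudError):
    """A rendered frame contains no visible surface."""


class StageError(PlantCloudError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
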