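"""Exception hierarchy shared across the package."""


class RotometryError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(RotometryError):
    """An STL file is malformed, truncated, or internally inconsistent."""


class InvalidInputError(RotometryError, ValueError):
    """An argument violates a documented precondition."""


class NotFoundError(RotometryError, KeyError):
    """A requested tooth / landmark / file is absent."""


class InvalidSegmentationError(RotometryError):
    """A tooth label set yields an empty or unusably small submesh."""


class DegenerateConfigurationError(RotometryError):
    """Geometric degeneracy: collinear points, zero-area plane basis, etc."""


class DegenerateVectorError(RotometryError):
    """A landmark vector has no usable projection onto the occlusal plane."""


class GenerationError(RotometryError):
    """The synthetic-arch generator received parameters it cannot realise."""


class UndefinedStatisticError(RotometryError):
    """A statistic is undefined for the given data (zero variance, etc.)."""


class StageError(RotometryError):
    """A pipeline stage is missing its upstream artifacts."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
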