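"""Exception types shared across the package."""


class MemeError(Exception):
    """Base class for all package-specific errors."""


class InvalidAnnotationError(MemeError):
    """The user annotation (mask / width) violates its contract."""


class LearningError(MemeError):
    """Appearance-model learning could not proceed (e.g. no admissible samples)."""


class ContractViolation(MemeError):
    """An operation was called with arguments that break its preconditions."""


class SkeletonizationError(MemeError):
    """Skeleton extraction failed on a structurally valid mask."""


class UnsupportedPostureError(SkeletonizationError):
    """The mask shows a coiled / closed-loop posture the tracer cannot handle."""


class DegenerateShapeWarning(UserWarning):
    """Raised (as a warning) when endpoint detection runs on a corner-free shape."""


class UndulationWarning(UserWarning):
    """Raised when a motility estimate is poorly resolved or undefined."""
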