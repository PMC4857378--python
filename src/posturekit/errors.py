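"""Exception hierarchy shared across the package."""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class InsufficientDataError(PostureKitError, ValueError):
    """Too few observations (marks, frames, values) for the requested computation."""


class DegenerateConfigurationError(PostureKitError, ValueError):
    """Input geometry admits no unique solution (collinear or duplicated points)."""


class DegenerateChordError(PostureKitError, ValueError):
    """The two limit points of a curvature chord coincide."""


class DegenerateAngleError(PostureKitError, ValueError):
    """An angle was requested with a zero-length ray."""


class ProjectionDomainError(PostureKitError, ValueError):
    """A 3D point lies at or behind the pinhole plane and cannot be projected."""


class UndefinedReferenceError(PostureKitError, ZeroDivisionError):
    """Percent error requested against a zero reference value."""


class ProtocolError(PostureKitError, ValueError):
    """A measurement protocol references unknown landmarks or invalid settings."""


class FormatError(PostureKitError, ValueError):
    """A data file does not conform to the expected dialect."""
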