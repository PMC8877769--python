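"""Exception hierarchy.

Every error raised by the package derives from :class:`FetalHCError`, so
callers can catch one type at a pipeline boundary.  Ellipse-fit failures
carry a distinct subclass per cause, because the segmentation route treats
an unusable segmentation (too few contour points, degenerate geometry,
non-elliptical conic) as a recoverable per-image failure rather than a bug.
"""


class FetalHCError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FetalHCError, ValueError):
    """A numeric argument violates its precondition (e.g. nonpositive axis)."""


class InvalidInputError(FetalHCError, ValueError):
    """An array input violates its contract (shape mismatch, out-of-range values)."""


class ConfigurationError(FetalHCError):
    """A required configuration value is unset or inconsistent."""


class EllipseFitError(FetalHCError):
    """Base class for ellipse-fit failures; segmentation route catches this."""


class TooFewPointsError(EllipseFitError):
    """Fewer than five contour points were available."""


class DegenerateGeometryError(EllipseFitError):
    """Points are collinear or otherwise rank-deficient."""


class NonEllipseError(EllipseFitError):
    """The least-squares conic is not an ellipse."""


class EmptyMaskError(FetalHCError):
    """An operation requiring a nonempty mask received an empty one."""


class InsufficientDataError(FetalHCError, ValueError):
    """Too few observations for the requested statistic."""
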