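"""Exception hierarchy for the velogrid measurement pipeline.

A measurement pipeline should fail loudly: degenerate geometry, points behind
the camera, or unrectified inputs raise rather than propagate NaN.
"""


class VelogridError(Exception):
    """Base class for all velogrid errors."""


class UnprojectablePointError(VelogridError):
    """A world point lies at or behind the camera plane (z <= 0)."""


class DistortionInversionError(VelogridError):
    """The radial-distortion fixed point / Newton iteration did not converge."""


class CalibrationError(VelogridError):
    """Calibration input is degenerate or underdetermined."""


class BorderPixelError(VelogridError):
    """Pixel dissimilarity requested at a scanline border without neighbors."""


class UnrectifiedInputError(VelogridError):
    """Stereo inputs disagree in shape or are otherwise not a rectified pair."""


class UnknownPackingError(VelogridError):
    """Composite stereo frame geometry does not match the declared packing."""


class UnsynchronizedSequencesError(VelogridError):
    """Left/right video sequences differ in length."""


class InvalidROIError(VelogridError):
    """Quadrangle ROI is degenerate, non-convex, or self-intersecting."""


class GridOutOfBoundsError(VelogridError):
    """A virtual-grid node falls outside the image raster."""


class EmptyFrameError(VelogridError):
    """No valid grid node is available in a frame."""


class EmptyRenderError(VelogridError):
    """The synthetic surface is entirely outside the camera field of view."""


class PipelineConfigError(VelogridError):
    """Pipeline configuration is invalid or references missing files."""
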