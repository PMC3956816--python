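"""Exception hierarchy for the CTXA pipeline.

Every stage raises a subclass of :class:`CTXAError` so the end-to-end driver
can attach the stage name and a remediation hint before re-raising.
"""


class CTXAError(Exception):
    """Base class for all pipeline errors."""


class GeometryError(CTXAError):
    """A requested region (rod disk, analysis box) lies outside the grid."""


class DegenerateFitError(CTXAError):
    """Calibration or regression input does not determine a unique fit."""


class OrientationError(CTXAError):
    """Principal axes are degenerate; manual shaft/neck angles are required."""


class LandmarkError(CTXAError):
    """Automatic ROI landmark detection failed; place ROIs manually."""


class UndefinedMeasureError(CTXAError):
    """A measurement was requested on an empty region."""


class FormatError(CTXAError):
    """An input file or series violates the expected on-disk format."""


class ResourceError(CTXAError):
    """An operation would exceed a configured memory bound."""
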