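"""Exception hierarchy shared by all measurement stages."""


class CentmorphError(Exception):
    """Base class for all centmorph errors."""


class DimensionError(CentmorphError):
    """Raster is not 2-D, or a multi-page file was read without a page index."""


class EmptyRegionError(CentmorphError):
    """An ROI or mask encloses no pixels."""


class GeometryError(CentmorphError):
    """A scan line, polygon or fiducial configuration is geometrically invalid."""


class OpenRingError(CentmorphError):
    """The thresholded ring is not closed around the declared center."""


class PeakDetectionError(CentmorphError):
    """An intensity profile lacks the two qualifying peaks needed for a diameter.

    Carries the offending profile on ``.profile`` for diagnostics.
    """

    def __init__(self, message, profile=None):
        super().__init__(message)
        self.profile = profile


class TruncatedPeakError(CentmorphError):
    """A peak's 90%-of-max level is never crossed on one side of the peak."""


class ThresholdInversionError(CentmorphError):
    """Background-derived lower threshold exceeds the upper threshold."""


class DegeneratePanelError(CentmorphError):
    """A membrane panel is entirely foreground or entirely background."""


class PackingError(CentmorphError):
    """Hole packing could not reach the target open fraction."""

    def __init__(self, message, achieved_fraction=None):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


class IneligibleTraceError(CentmorphError):
    """A microtubule trace does not cross the interior boundary line."""


class InsufficientDataError(CentmorphError):
    """Too few observations for the requested statistic."""
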