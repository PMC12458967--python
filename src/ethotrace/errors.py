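"""Exception hierarchy.

Every error raised by the package derives from :class:`EthotraceError` so
callers can catch the package's failures with a single except clause while
still distinguishing I/O, geometry and statistics problems.
"""


class EthotraceError(Exception):
    """Base class for all ethotrace errors."""


class FormatError(EthotraceError):
    """Malformed on-disk input (missing column, inconsistent frame sizes...)."""


class SamplingError(EthotraceError):
    """Non-uniform or gapped temporal sampling."""


class IntegrityError(EthotraceError):
    """Internally inconsistent data (duplicate keys, non-finite coordinates)."""


class BinarizationError(EthotraceError):
    """Mask stack contains non-binary pixels and no threshold was configured."""


class GeometryError(EthotraceError):
    """Degenerate or out-of-bounds geometry (zero-length midline, off-image raster)."""


class SegmentationError(EthotraceError):
    """Mask does not contain exactly one usable foreground component."""


class CoiledFrameError(SegmentationError):
    """Skeleton has >2 endpoints after pruning; frame should be dropped, not fatal."""


class ParameterError(EthotraceError):
    """Invalid user-supplied parameter value."""


class StatisticsError(EthotraceError):
    """Statistical routine called on insufficient or empty data."""


class DesignError(StatisticsError):
    """Test design violated (e.g. paired groups of unequal length)."""


class FitError(StatisticsError):
    """Model fit failed to converge; diagnostics attached to the message."""


class AlignmentError(EthotraceError):
    """Two series share no common timestamps."""


class EmptyDensityError(StatisticsError):
    """Density requested for an empty point set."""


class ReportError(EthotraceError):
    """Report rendering is missing required pieces; message lists them."""
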