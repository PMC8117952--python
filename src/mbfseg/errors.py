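"""Exception hierarchy for the segmentation pipeline.

Fatal conditions (the study-level abort contract) derive from
:class:`PipelineAbort`; everything else derives from :class:`MbfsegError`.
"""


class MbfsegError(Exception):
    """Base class for all package errors."""


class PipelineAbort(MbfsegError):
    """Errors that abort processing of a slice or study."""


# --- I/O -------------------------------------------------------------------

class MissingMetadata(Warning):
    """Non-fatal: spacing/timing metadata absent, defaults applied."""


class MalformedSeries(MbfsegError):
    """Dynamic series frames have inconsistent shapes or dimensions."""


class NegativeFlow(MbfsegError):
    """An MBF map contains negative values beyond tolerance."""


class SchemaError(MbfsegError):
    """A segmentation JSON document does not match the expected schema."""


# --- landmark / ventricle detection ---------------------------------------

class LVNotFound(PipelineAbort):
    """The left-ventricular blood pool could not be located (fatal)."""


class RVNotFound(MbfsegError):
    """The right-ventricular blood pool could not be located (non-fatal)."""


class MissingRV(MbfsegError):
    """RV insertion detection requested without an RV mask."""


# --- perfusion-image segmentation -----------------------------------------

class ArrivalNotFound(PipelineAbort):
    """No contrast-arrival frame could be identified from the LV curve."""


class GrowthOverflow(MbfsegError):
    """Region growing leaked into the background (>40% of the image)."""


class NoEdgeFound(PipelineAbort):
    """Polar Canny produced no edge chain with sufficient angular coverage."""


class InsufficientFrames(MbfsegError):
    """Too few washout frames for principal-component reconstruction."""


class DegenerateContour(PipelineAbort):
    """An active contour collapsed or could not be kept simple."""


# --- map segmentation ------------------------------------------------------

class EmptyBloodPool(PipelineAbort):
    """Blood-pool region growing on the MBF map found almost nothing."""


# --- phantom ---------------------------------------------------------------

class DomainError(MbfsegError):
    """Invalid parameter domain (e.g. non-positive gamma-variate shape)."""


class GeometryError(MbfsegError):
    """Phantom regions overlap inconsistently or do not fit the image."""


# --- sectors / metrics -----------------------------------------------------

class SectorMismatch(MbfsegError):
    """Two sector reports use different sector models."""


class EmptyReference(MbfsegError):
    """Reference mask empty; ratio metrics undefined."""


class ZeroVariance(MbfsegError):
    """Correlation undefined because one sequence has zero variance."""


class SingularCovariance(MbfsegError):
    """Pooled covariance is singular (e.g. collinear point sets)."""
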