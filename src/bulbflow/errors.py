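"""Typed exception hierarchy.

Every reader/operation rejects invalid input with one of these, so callers
(and the pipeline's per-subject error isolation) can distinguish malformed
files from geometric or statistical degeneracies.
"""


class BulbflowError(Exception):
    """Base class for all bulbflow errors."""


class ParameterError(BulbflowError, ValueError):
    """A scalar parameter violates its contract (ordering, sign, range)."""


class MeshFormatError(BulbflowError):
    """Malformed mesh/field file; message names the offending line."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnsupportedCellError(MeshFormatError):
    """The file contains a cell type other than tetrahedra/triangles."""


class TopologyError(BulbflowError):
    """Mesh connectivity or boundary-matching violation."""


class OrderError(BulbflowError, ValueError):
    """A sequence that must be strictly increasing is not."""


class SizeError(BulbflowError, ValueError):
    """Too few samples/rows/groups for the operation."""


class GeometryError(BulbflowError):
    """A geometric precondition fails (e.g. pocket outside the lumen)."""


class UnsupportedGeometryError(GeometryError):
    """The mesh lacks the axis metadata an operation needs."""


class ExtractionError(BulbflowError):
    """Centerline marching failed; carries the last good arclength."""

    def __init__(self, message, last_arclength=None):
        super().__init__(message)
        self.last_arclength = last_arclength


class InsufficientExtentError(BulbflowError, ValueError):
    """Radius profile too short to estimate a reference diameter."""


class EmptyRegionError(BulbflowError):
    """An ROI with no member faces/cells was passed to a metric."""


class DegenerateLabelError(BulbflowError, ValueError):
    """ROC analysis needs both positive and negative labels."""


class IntegrationError(BulbflowError):
    """The 0D Windkessel integration produced non-finite pressure."""


class ConsistencyWarning(UserWarning):
    """Redundant inputs disagree (e.g. stated vs waveform mean flow)."""
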