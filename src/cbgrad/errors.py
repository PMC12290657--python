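"""Exception hierarchy shared across the pipeline stages."""


class CbgradError(Exception):
    """Base class for all package-specific errors."""


class SizingError(CbgradError):
    """Requested phantom grid cannot hold the folded sheet."""


class DesignError(CbgradError):
    """Task design or design matrix is invalid."""


class BoundaryError(CbgradError):
    """A boundary mask came out empty or otherwise unusable."""


class AdjacencyError(BoundaryError):
    """Two label regions expected to touch do not."""


class ConnectivityError(CbgradError):
    """Too many ROI voxels unreachable from a gradient boundary."""


class ShapeError(CbgradError):
    """Volumes or tables with incompatible shapes were combined."""


class ReferenceError_(CbgradError):
    """An effect or config entry references a label that does not exist."""


class DegenerateInputError(CbgradError):
    """A statistical routine received input with no usable variance."""
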