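"""Exception types shared across the pipeline."""


class PclEvalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PclEvalError):
    """A file or header violates the expected format (non-3D image, bad spacing, ...)."""


class AlignmentError(PclEvalError):
    """Two grids that must share geometry do not."""


class ValidationError(PclEvalError):
    """An in-memory object violates its invariants."""


class PlacementError(PclEvalError):
    """A synthetic structure cannot be placed inside the phantom geometry."""


class SegmentationFailedError(PclEvalError):
    """The organ mask is empty; mirrors a failed first-stage organ segmentation."""


class DegenerateGeometryError(PclEvalError):
    """Mask geometry too thin/small for centerline extraction."""


class EmptySphereError(PclEvalError):
    """A voxelized annotation sphere contains no voxel centers."""


class UndefinedDiceError(PclEvalError):
    """Dice overlap of two empty voxel sets is undefined."""
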