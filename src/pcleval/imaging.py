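"""NIfTI-backed volume and label-mask containers.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)``;
* world coordinates are millimetres in RAS+ orientation (``+x`` right,
  ``+y`` anterior, ``+z`` superior); images are reoriented to the closest
  canonical (RAS) frame on load;
* the last axis (``k``) is the axial/slice axis after reorientation;
* the world position of a voxel center is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError

#: relative tolerance for declaring two voxel spacings equal (header round-off)
SPACING_RTOL = 1e-4

MASK_SEMANTICS = ("pancreas", "duct", "cyst_semantic", "cyst_instance", "region")


def _validate_geometry(shape, spacing) -> None:
    if len(shape) != 3:
        raise FormatError(f"expected a 3D grid, got shape {shape}")
    if any(s < 1 for s in shape):
        raise FormatError(f"every grid dimension must be >= 1, got {shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise FormatError(f"spacing must have three components, got {spacing}")
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise FormatError(f"spacing components must be positive and finite, got {spacing}")


@dataclass
class VolumeImage:
    """A 3D scalar grid in Hounsfield units with physical geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _validate_geometry(self.voxels.shape, self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centers for an (N, 3) index array."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)


@dataclass
class LabelMask:
    """Integer labels on the same grid as a reference :class:`VolumeImage`.

    Label 0 is background. ``semantics`` states what nonzero labels mean.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantics: str = "cyst_semantic"
    axis_codes: str = "RAS"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _validate_geometry(self.labels.shape, self.spacing)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.int32)
            else:
                rounded = np.rint(self.labels)
                if not np.array_equal(rounded, self.labels):
                    raise ValidationError("labels must be integers")
                self.labels = rounded.astype(np.int32)
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative; 0 is background")
        if self.semantics not in MASK_SEMANTICS:
            raise ValidationError(f"unknown mask semantics {self.semantics!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def _load_canonical(path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {img.ndim}D")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = nib.affines.voxel_sizes(img.affine)
    origin = img.affine[:3, 3]
    _validate_geometry(data.shape, spacing)
    return data, tuple(float(s) for s in spacing), tuple(float(o) for o in origin)


def read_volume(path) -> VolumeImage:
    """Read a NIfTI scalar volume, reoriented to RAS."""
    data, spacing, origin = _load_canonical(path)
    return VolumeImage(voxels=data.astype(np.float32, copy=False), spacing=spacing, origin=origin)


def read_mask(path, semantics: str = "cyst_semantic") -> LabelMask:
    """Read a NIfTI label mask, reoriented to RAS."""
    data, spacing, origin = _load_canonical(path)
    return LabelMask(labels=data, spacing=spacing, origin=origin, semantics=semantics)


def write_volume(obj: VolumeImage | LabelMask, path) -> None:
    """Write a volume or mask as NIfTI-1, readable back by :func:`read_volume`/:func:`read_mask`."""
    if isinstance(obj, LabelMask):
        if obj.labels.size and obj.labels.min() < 0:
            raise ValidationError("refusing to write mask with negative labels")
        data = obj.labels.astype(np.int32, copy=False)
    elif isinstance(obj, VolumeImage):
        data = obj.voxels.astype(np.float32, copy=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    img = nib.Nifti1Image(data, _affine(obj.spacing, obj.origin))
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))


def check_aligned(a: VolumeImage | LabelMask, b: VolumeImage | LabelMask) -> bool:
    """True iff the two grids have equal shape and spacing (relative tol 1e-4)."""
    if a.shape != b.shape:
        return False
    return bool(np.allclose(a.spacing, b.spacing, rtol=SPACING_RTOL, atol=0.0))


def require_aligned(*objs) -> None:
    from .errors import AlignmentError

    first = objs[0]
    for other in objs[1:]:
        if not check_aligned(first, other):
            raise AlignmentError(
                f"grids not aligned: shape/spacing {first.shape}/{first.spacing} "
                f"vs {other.shape}/{other.spacing}"
            )
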