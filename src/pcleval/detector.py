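"""Two-step candidate detection: crop the CT to the organ, then segment cysts.

The detector here is a transparent classical surrogate (Gaussian smoothing +
HU window inside the dilated organ mask + duct suppression + minimum-volume
filter). It produces exactly the interface downstream evaluation consumes —
a binary candidate mask aligned to the CT — so the output of a trained
segmentation network can be dropped in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SegmentationFailedError, ValidationError
from .imaging import LabelMask, VolumeImage, require_aligned
from .instances import STRUCT_26


@dataclass
class DetectorConfig:
    """Surrogate detector parameters.

    The HU window brackets fluid density (cysts ≈ 0–20 HU) against enhancing
    parenchyma (≈ 50 HU); the minimum volume mirrors the 10 mm³ evaluation
    floor applied to ground truth.
    """

    hu_low: float = -20.0
    hu_high: float = 25.0
    smoothing_radius_mm: float = 1.0
    pancreas_dilation_mm: float = 2.0
    min_volume_mm3: float = 10.0
    suppress_duct: bool = True

    def __post_init__(self):
        if not self.hu_low < self.hu_high:
            raise ValidationError("hu_low must be strictly below hu_high")
        if self.min_volume_mm3 <= 0:
            raise ValidationError("min_volume_mm3 must be positive")
        if self.smoothing_radius_mm < 0 or self.pancreas_dilation_mm < 0:
            raise ValidationError("smoothing and dilation radii must be non-negative")


def crop_to_organ(
    ct: VolumeImage, organ: LabelMask, margin_slices: int = 0
) -> tuple[VolumeImage, LabelMask, tuple[int, int]]:
    """Crop to the axial slices that show the organ.

    Returns the cropped CT, the cropped organ mask, and the inclusive slice
    range ``(z0, z1)`` in the original grid for mapping results back. An
    empty organ mask raises :class:`SegmentationFailedError` (the analogue
    of a failed first-stage organ segmentation).
    """
    require_aligned(ct, organ)
    if margin_slices < 0:
        raise ValidationError("margin_slices must be >= 0")
    nz = np.nonzero(np.any(organ.labels > 0, axis=(0, 1)))[0]
    if nz.size == 0:
        raise SegmentationFailedError("organ mask is empty: segmentation failed")
    z0 = max(int(nz[0]) - margin_slices, 0)
    z1 = min(int(nz[-1]) + margin_slices, ct.shape[2] - 1)
    new_origin = (ct.origin[0], ct.origin[1], ct.origin[2] + z0 * ct.spacing[2])
    ct_c = VolumeImage(ct.voxels[:, :, z0 : z1 + 1], ct.spacing, new_origin)
    organ_c = LabelMask(organ.labels[:, :, z0 : z1 + 1], organ.spacing, new_origin, organ.semantics)
    return ct_c, organ_c, (z0, z1)


def apply_crop(mask: LabelMask, slice_range: tuple[int, int]) -> LabelMask:
    """Apply a slice range from :func:`crop_to_organ` to another aligned mask."""
    z0, z1 = slice_range
    new_origin = (mask.origin[0], mask.origin[1], mask.origin[2] + z0 * mask.spacing[2])
    return LabelMask(mask.labels[:, :, z0 : z1 + 1], mask.spacing, new_origin, mask.semantics)


def detect_candidates(
    ct: VolumeImage,
    organ: LabelMask,
    duct: LabelMask | None = None,
    cfg: DetectorConfig | None = None,
) -> LabelMask:
    """Binary cyst-candidate mask from HU windowing inside the dilated organ.

    Hysteresis segmentation inside the dilated organ: *seed* voxels must fall
    in ``[hu_low, hu_high]`` after Gaussian smoothing (robust against noise,
    but eroded at lesion boundaries where smoothing mixes in parenchyma);
    the candidate *extent* is the 26-connected component of raw-HU-window
    voxels containing a seed (recovering the sharp boundary). Both gates are
    restricted to the organ mask dilated by ``pancreas_dilation_mm``, which
    also suppresses the partial-volume shell at the organ surface. Duct
    voxels are removed when ``suppress_duct``; components under
    ``min_volume_mm3`` are discarded.
    """
    cfg = cfg or DetectorConfig()
    require_aligned(ct, organ)
    if duct is not None:
        require_aligned(ct, duct)
    spacing = np.asarray(ct.spacing)

    raw = ct.voxels.astype(np.float32, copy=False)
    hu = raw
    if cfg.smoothing_radius_mm > 0:
        hu = ndimage.gaussian_filter(raw, sigma=cfg.smoothing_radius_mm / spacing)

    inside = organ.labels > 0
    if cfg.pancreas_dilation_mm > 0:
        dist_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
        inside = dist_out <= cfg.pancreas_dilation_mm

    extent = inside & (raw >= cfg.hu_low) & (raw <= cfg.hu_high)
    seeds = extent & (hu >= cfg.hu_low) & (hu <= cfg.hu_high)
    if cfg.suppress_duct and duct is not None:
        duct_vox = duct.labels > 0
        extent &= ~duct_vox
        seeds &= ~duct_vox

    labeled, n = ndimage.label(extent, structure=STRUCT_26)
    cand = np.zeros_like(extent)
    if n:
        seeded = np.zeros(n + 1, dtype=bool)
        seeded[np.unique(labeled[seeds])] = True
        seeded[0] = False
        counts = np.bincount(labeled.ravel(), minlength=n + 1)
        keep = seeded & (counts * ct.voxel_volume >= cfg.min_volume_mm3)
        cand = keep[labeled]
    return LabelMask(cand, ct.spacing, ct.origin, semantics="cyst_semantic")
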