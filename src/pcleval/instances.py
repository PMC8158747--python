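"""Lesion-instance extraction and Dice-based detection matching.

A binary lesion segmentation is turned into instances by 26-connected
component analysis; a ground-truth lesion counts as detected when some
predicted instance overlaps it with a Dice–Sørensen coefficient (DSC) of at
least the detection threshold (0.30 for model evaluation, 0.10 for the
sphere-based reader protocol). Ground-truth lesions below a physical volume
floor (10 mm³ by default) are excluded from evaluation altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import UndefinedDiceError, ValidationError
from .imaging import LabelMask

#: 26-neighbourhood structuring element for 3D connected components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: evaluation floor from the study protocol: lesions under 10 mm³ are excluded
DEFAULT_VOLUME_FLOOR_MM3 = 10.0

#: detection criterion: DSC >= 0.30 between prediction and ground truth
DEFAULT_DSC_THRESHOLD = 0.30


@dataclass(frozen=True)
class LesionInstance:
    """One connected lesion on a voxel grid.

    ``voxel_ids`` are flat (raveled, C-order) indices into the grid of
    ``grid_shape``; ``volume_mm3`` is exactly ``len(voxel_ids) * voxel_volume``.
    """

    id: int
    voxel_ids: frozenset[int]
    grid_shape: tuple[int, int, int]
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    source: str = "gt"  # gt | pred

    def __post_init__(self):
        if not self.voxel_ids:
            raise ValidationError("lesion instance must have a nonempty voxel set")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class MatchResult:
    """One-to-one GT↔prediction pairing under the DSC detection criterion."""

    pairs: list[tuple[int, int, float]]
    fn_gt_ids: list[int]
    fp_pred_ids: list[int]
    excluded_gt_ids: list[int]
    dropped_pred_ids: list[int]
    dsc_threshold: float

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fn(self) -> int:
        return len(self.fn_gt_ids)

    @property
    def n_fp(self) -> int:
        return len(self.fp_pred_ids)


def _voxel_set(obj) -> frozenset[int]:
    if isinstance(obj, LesionInstance):
        return obj.voxel_ids
    return frozenset(int(i) for i in obj)


def dice(a, b) -> float:
    """Dice–Sørensen coefficient 2|A∩B| / (|A|+|B|) of two voxel sets.

    Accepts raw index sets or :class:`LesionInstance` objects. Undefined
    (raises) when both sets are empty.
    """
    sa, sb = _voxel_set(a), _voxel_set(b)
    if not sa and not sb:
        raise UndefinedDiceError("Dice of two empty sets is undefined")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def extract_instances(
    mask: LabelMask,
    min_volume_mm3: float = DEFAULT_VOLUME_FLOOR_MM3,
    source: str = "gt",
) -> list[LesionInstance]:
    """26-connected components of a binary mask, filtered by physical volume.

    Instances are id'd 1..n in descending volume order; ties are broken by
    lexicographic centroid so the ordering is independent of scan order.
    An empty mask yields an empty list.
    """
    binary = mask.labels > 0
    labeled, n = ndimage.label(binary, structure=STRUCT_26)
    if n == 0:
        return []
    vox_vol = mask.voxel_volume
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    flat = labeled.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    # contiguous runs of each component's flat voxel indices
    boundaries = np.searchsorted(sorted_labels, np.arange(1, n + 2))
    shape = mask.shape
    candidates = []
    for comp in range(1, n + 1):
        idx = order[boundaries[comp - 1] : boundaries[comp]]
        vol = idx.size * vox_vol
        if vol < min_volume_mm3:
            continue
        coords = np.stack(np.unravel_index(idx, shape), axis=1)
        centroid = tuple(origin + coords.mean(axis=0) * spacing)
        candidates.append((vol, centroid, idx))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return [
        LesionInstance(
            id=i + 1,
            voxel_ids=frozenset(int(v) for v in idx),
            grid_shape=shape,
            volume_mm3=vol,
            centroid_mm=centroid,
            source=source,
        )
        for i, (vol, centroid, idx) in enumerate(candidates)
    ]


def match_detections(
    gt: list[LesionInstance],
    pred: list[LesionInstance],
    dsc_threshold: float = DEFAULT_DSC_THRESHOLD,
    gt_volume_floor_mm3: float = 0.0,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth by descending DSC.

    A pair is accepted only at DSC >= ``dsc_threshold``; ties are broken by
    smaller gt id, then smaller pred id, making the result deterministic and
    independent of input order. GT instances below ``gt_volume_floor_mm3``
    are excluded from evaluation; predictions whose only above-threshold
    overlap is with excluded GT are dropped (neither TP nor FP).
    """
    if not 0.0 < dsc_threshold <= 1.0:
        raise ValidationError("dsc_threshold must lie in (0, 1]")
    gt_ids = [g.id for g in gt]
    pred_ids = [p.id for p in pred]
    if len(set(gt_ids)) != len(gt_ids) or len(set(pred_ids)) != len(pred_ids):
        raise ValidationError("instance ids must be unique within each list")

    excluded = {g.id for g in gt if g.volume_mm3 < gt_volume_floor_mm3}
    eligible = [g for g in gt if g.id not in excluded]

    # all above-threshold candidate pairs over eligible GT
    cand = []
    for g in eligible:
        for p in pred:
            d = dice(g, p)
            if d >= dsc_threshold:
                cand.append((d, g.id, p.id))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))

    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, gid, pid in cand:
        if gid in matched_gt or pid in matched_pred:
            continue
        pairs.append((gid, pid, d))
        matched_gt.add(gid)
        matched_pred.add(pid)

    # predictions matching only excluded GT are dropped from FP entirely
    dropped: set[int] = set()
    excluded_insts = [g for g in gt if g.id in excluded]
    for p in pred:
        if p.id in matched_pred:
            continue
        if any(dice(g, p) >= dsc_threshold for g in excluded_insts):
            dropped.add(p.id)

    fn = sorted(g.id for g in eligible if g.id not in matched_gt)
    fp = sorted(p.id for p in pred if p.id not in matched_pred and p.id not in dropped)
    return MatchResult(
        pairs=pairs,
        fn_gt_ids=fn,
        fp_pred_ids=fp,
        excluded_gt_ids=sorted(excluded),
        dropped_pred_ids=sorted(dropped),
        dsc_threshold=dsc_threshold,
    )


def attribute_fp_to_duct(
    fp: list[LesionInstance], duct: LabelMask
) -> tuple[int, float | None]:
    """Count false positives caused by the main pancreatic duct.

    An FP is duct-caused when strictly more than 50% of its voxels lie on
    nonzero duct labels. Returns ``(count, percent)`` with the percentage
    rounded to one decimal; ``percent`` is None when there are no FPs.
    """
    if not fp:
        return 0, None
    duct_flat = duct.labels.ravel() > 0
    count = 0
    for inst in fp:
        ids = np.fromiter(inst.voxel_ids, dtype=np.int64)
        on_duct = int(duct_flat[ids].sum())
        if on_duct * 2 > inst.n_voxels:
            count += 1
    return count, duct_fp_percent(count, len(fp))


def duct_fp_percent(n_duct: int, n_total: int) -> float | None:
    """Percentage of FPs attributed to the duct, rounded to one decimal."""
    if n_total == 0:
        return None
    return round(100.0 * n_duct / n_total, 1)


def instances_to_mask(
    instances: list[LesionInstance],
    spacing,
    origin=(0.0, 0.0, 0.0),
    semantics: str = "cyst_instance",
) -> LabelMask:
    """Paint instances back onto a grid (instance id per voxel)."""
    if not instances:
        raise ValidationError("cannot infer grid shape from an empty instance list")
    shape = instances[0].grid_shape
    out = np.zeros(shape, dtype=np.int32)
    flat = out.ravel()
    for inst in instances:
        ids = np.fromiter(inst.voxel_ids, dtype=np.int64)
        flat[ids] = inst.id
    return LabelMask(labels=out, spacing=spacing, origin=origin, semantics=semantics)
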