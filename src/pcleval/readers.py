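"""Human-reader comparison protocol.

Readers annotate each lesion's greatest linear diameter; a 3D sphere is
voxelized around that diameter (center = segment midpoint, radius =
half-diameter, voxel-center inclusion) and matched against ground-truth
instances one-to-one at a lenient DSC threshold of 0.10. Per reader this
yields sensitivity and false positives per case, directly comparable with
the model's instance-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySphereError, ValidationError
from .imaging import LabelMask, VolumeImage
from .instances import LesionInstance, match_detections
from .phantom import PhantomTruth, sphere_radius_for_volume, _ellipsoid_voxels

#: reader detection criterion: sphere vs GT overlap of at least 10% DSC
READER_DSC_THRESHOLD = 0.10

ANNOTATION_COLUMNS = ["case_id", "reader_id", "x1_mm", "y1_mm", "z1_mm", "x2_mm", "y2_mm", "z2_mm"]


@dataclass(frozen=True)
class ReaderAnnotation:
    """One annotated linear diameter: endpoints in world mm."""

    case_id: str
    reader_id: str
    p1_mm: tuple[float, float, float]
    p2_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValidationError("annotated diameter must be positive")

    @property
    def diameter_mm(self) -> float:
        return float(np.linalg.norm(np.asarray(self.p1_mm) - np.asarray(self.p2_mm)))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple((np.asarray(self.p1_mm) + np.asarray(self.p2_mm)) / 2.0)


def load_annotations(path) -> list[ReaderAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {sorted(missing)}")
    return [
        ReaderAnnotation(
            case_id=str(r.case_id),
            reader_id=str(r.reader_id),
            p1_mm=(r.x1_mm, r.y1_mm, r.z1_mm),
            p2_mm=(r.x2_mm, r.y2_mm, r.z2_mm),
        )
        for r in df.itertuples()
    ]


def save_annotations(annotations: list[ReaderAnnotation], path) -> None:
    rows = [
        {
            "case_id": a.case_id,
            "reader_id": a.reader_id,
            "x1_mm": a.p1_mm[0],
            "y1_mm": a.p1_mm[1],
            "z1_mm": a.p1_mm[2],
            "x2_mm": a.p2_mm[0],
            "y2_mm": a.p2_mm[1],
            "z2_mm": a.p2_mm[2],
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def sphere_mask(annotation: ReaderAnnotation, geometry: VolumeImage | LabelMask) -> frozenset[int]:
    """Flat voxel ids whose centers lie within the annotation's sphere."""
    r = annotation.diameter_mm / 2.0
    ids = _ellipsoid_voxels(annotation.center_mm, (r, r, r), geometry.shape, geometry.spacing, geometry.origin)
    if ids.size == 0:
        # a diameter smaller than the voxel grid pitch still marks one voxel
        idx = np.rint((np.asarray(annotation.center_mm) - np.asarray(geometry.origin)) / np.asarray(geometry.spacing))
        if np.any(idx < 0) or np.any(idx >= np.asarray(geometry.shape)):
            raise EmptySphereError("annotation sphere lies entirely outside the grid")
        ids = np.asarray([np.ravel_multi_index(tuple(idx.astype(int)), geometry.shape)])
    return frozenset(int(i) for i in ids)


def annotations_to_instances(
    annotations: list[ReaderAnnotation], geometry: VolumeImage | LabelMask
) -> list[LesionInstance]:
    """Voxelize one sphere instance per annotation (ids in input order)."""
    spacing = np.asarray(geometry.spacing)
    origin = np.asarray(geometry.origin)
    out = []
    for i, ann in enumerate(annotations, start=1):
        ids = sphere_mask(ann, geometry)
        arr = np.fromiter(ids, dtype=np.int64)
        coords = np.stack(np.unravel_index(arr, geometry.shape), axis=1)
        centroid = tuple(origin + coords.mean(axis=0) * spacing)
        out.append(
            LesionInstance(
                id=i,
                voxel_ids=ids,
                grid_shape=geometry.shape,
                volume_mm3=len(ids) * float(np.prod(spacing)),
                centroid_mm=centroid,
                source="pred",
            )
        )
    return out


def evaluate_readers(
    annotations: list[ReaderAnnotation],
    cases: dict[str, tuple[VolumeImage | LabelMask, list[LesionInstance]]],
    dsc_threshold: float = READER_DSC_THRESHOLD,
) -> pd.DataFrame:
    """Per-reader sensitivity and FPs/case against ground-truth instances.

    ``cases`` maps case id to ``(geometry, gt_instances)``. Every reader is
    evaluated on every case; spheres are matched one-to-one to GT greedily
    by descending DSC at ``dsc_threshold``.
    """
    known = set(cases)
    for a in annotations:
        if a.case_id not in known:
            raise ValidationError(f"annotation references unknown case {a.case_id!r}")
    readers = sorted({a.reader_id for a in annotations})
    n_cases = len(cases)
    rows = []
    for reader in readers:
        tp = fp = fn = 0
        for case_id, (geometry, gt) in cases.items():
            anns = [a for a in annotations if a.reader_id == reader and a.case_id == case_id]
            spheres = annotations_to_instances(anns, geometry)
            m = match_detections(gt, spheres, dsc_threshold=dsc_threshold)
            tp += m.n_tp
            fp += m.n_fp
            fn += m.n_fn
        rows.append(
            {
                "reader_id": reader,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "n_cases": n_cases,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "fp_per_case": fp / n_cases,
            }
        )
    return pd.DataFrame(rows)


def simulate_reader(
    truth: PhantomTruth,
    case_id: str,
    reader_id: str = "sim",
    miss_prob: float = 0.0,
    center_sigma_mm: float = 0.5,
    diameter_rel_sigma: float = 0.05,
    seed: int = 0,
) -> list[ReaderAnnotation]:
    """Synthetic reader: annotates each GT cyst's equivalent diameter with
    configurable jitter and a per-lesion miss probability. All randomness is
    seeded; no spurious (false-positive) annotations are generated.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _, row in truth.catalogue.iterrows():
        if rng.random() < miss_prob:
            continue
        d = 2.0 * sphere_radius_for_volume(row["volume_mm3"])
        d = max(d * (1.0 + rng.normal(0.0, diameter_rel_sigma)), 0.5)
        center = np.asarray([row["cx_mm"], row["cy_mm"], row["cz_mm"]])
        center = center + rng.normal(0.0, center_sigma_mm, size=3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        out.append(
            ReaderAnnotation(
                case_id=case_id,
                reader_id=reader_id,
                p1_mm=tuple(center - u * d / 2.0),
                p2_mm=tuple(center + u * d / 2.0),
            )
        )
    return out
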