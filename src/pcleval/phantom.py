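"""Seeded CT-like phantoms of a curved pancreas with duct, cysts and confounders.

The phantom is the testbed for the whole evaluation pipeline: a curved tube
of parenchyma (~50 HU) in a fat-like background (−80 HU), a thin hypodense
main pancreatic duct running along the tube axis, hypodense cyst instances
(spheres/ellipsoids voxelized by voxel-center inclusion) with an exact
ground-truth catalogue, optional cyst-mimicking confounders outside the
organ, and additive Gaussian noise. Identical spec + seed give bit-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import PlacementError, ValidationError
from .imaging import LabelMask, VolumeImage

#: volume-group boundaries (mm³) used to stratify cysts: [10,50], (50,200], (200,600], (600,·]
GROUP_EDGES_MM3 = (10.0, 50.0, 200.0, 600.0)
#: sampling cap for the open-ended largest group
GROUP_UPPER_CAP_MM3 = 5000.0


@dataclass(frozen=True)
class CystSpec:
    """A cyst to render: target physical volume, world-mm center, HU value."""

    target_volume_mm3: float
    center_mm: tuple[float, float, float]
    hu: float = 10.0
    axes_ratio: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class ConfounderSpec:
    """A cyst-mimicking structure outside the pancreas (blob or short tube)."""

    volume_mm3: float
    center_mm: tuple[float, float, float]
    hu: float = 10.0
    kind: str = "blob"  # blob | tube


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    pancreas_curve: list[tuple[float, float, float]]
    pancreas_radius_mm: float | tuple[float, float] = 12.0
    parenchyma_hu: float = 50.0
    duct_radius_mm: float = 1.0
    duct_hu: float = 5.0
    cysts: list[CystSpec] = field(default_factory=list)
    confounders: list[ConfounderSpec] = field(default_factory=list)
    noise_sigma_hu: float = 0.0
    background_hu: float = -80.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth of a rendered phantom."""

    cyst_instances: LabelMask
    duct_mask: LabelMask
    pancreas_mask: LabelMask
    catalogue: pd.DataFrame  # columns: id, volume_mm3, cx_mm, cy_mm, cz_mm, hu
    seed: int


def sphere_radius_for_volume(volume_mm3: float) -> float:
    """Radius of a sphere of the given volume."""
    return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def densify_polyline(points, step_mm: float) -> np.ndarray:
    """Resample a piecewise-linear curve at ~step_mm arc-length intervals."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValidationError("pancreas_curve needs at least two 3D control points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("pancreas_curve has zero length")
    n = max(int(np.ceil(total / step_mm)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)


def polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _radius_profile(spec: PhantomSpec, frac: np.ndarray) -> np.ndarray:
    r = spec.pancreas_radius_mm
    if np.isscalar(r):
        return np.full_like(np.asarray(frac, dtype=float), float(r))
    r0, r1 = r
    return r0 + (r1 - r0) * np.asarray(frac, dtype=float)


def _voxel_center_grid(shape, spacing, origin):
    ax = [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid_voxels(center, semi_axes, shape, spacing, origin):
    """Flat indices of voxels whose centers lie inside the ellipsoid."""
    lo, hi = [], []
    for k in range(3):
        lo.append(max(int(np.floor((center[k] - semi_axes[k] - origin[k]) / spacing[k])), 0))
        hi.append(min(int(np.ceil((center[k] + semi_axes[k] - origin[k]) / spacing[k])) + 1, shape[k]))
    if any(lo[k] >= hi[k] for k in range(3)):
        return np.empty(0, dtype=np.int64)
    ax = [origin[k] + np.arange(lo[k], hi[k]) * spacing[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    q = (
        ((X - center[0]) / semi_axes[0]) ** 2
        + ((Y - center[1]) / semi_axes[1]) ** 2
        + ((Z - center[2]) / semi_axes[2]) ** 2
    )
    ii, jj, kk = np.nonzero(q <= 1.0)
    return np.ravel_multi_index((ii + lo[0], jj + lo[1], kk + lo[2]), shape).astype(np.int64)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Render the phantom CT and its ground truth masks/catalogue."""
    shape, spacing, origin = tuple(spec.grid_shape), tuple(spec.spacing), tuple(spec.origin)
    step = min(spacing) / 2.0
    curve = densify_polyline(spec.pancreas_curve, step)
    arcs = polyline_arclengths(curve)
    total_len = arcs[-1]
    max_r = float(np.max(_radius_profile(spec, np.array([0.0, 1.0]))))

    # distance of every voxel center (inside the curve's bounding box) to the curve
    pad = max_r + 2.0 * max(spacing)
    lo_idx = [max(int(np.floor((curve[:, k].min() - pad - origin[k]) / spacing[k])), 0) for k in range(3)]
    hi_idx = [
        min(int(np.ceil((curve[:, k].max() + pad - origin[k]) / spacing[k])) + 1, shape[k])
        for k in range(3)
    ]
    sub_shape = tuple(hi_idx[k] - lo_idx[k] for k in range(3))
    sub_origin = tuple(origin[k] + lo_idx[k] * spacing[k] for k in range(3))
    X, Y, Z = _voxel_center_grid(sub_shape, spacing, sub_origin)
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tree = cKDTree(curve)
    dist, nearest = tree.query(pts, workers=-1)
    frac = arcs[nearest] / total_len
    radius_here = _radius_profile(spec, frac)

    pancreas_sub = dist <= radius_here
    duct_sub = dist <= spec.duct_radius_mm

    pancreas = np.zeros(shape, dtype=bool)
    duct = np.zeros(shape, dtype=bool)
    sl = tuple(slice(lo_idx[k], hi_idx[k]) for k in range(3))
    pancreas[sl] = pancreas_sub.reshape(sub_shape)
    duct[sl] = duct_sub.reshape(sub_shape)

    # cysts: voxelized ellipsoids, pairwise disjoint, centered inside the tube
    instances = np.zeros(shape, dtype=np.int32)
    inst_flat = instances.ravel()
    rows = []
    vox_vol = float(np.prod(spacing))
    fit_tol = max(spacing)
    for i, cyst in enumerate(spec.cysts, start=1):
        if cyst.target_volume_mm3 < vox_vol:
            raise PlacementError(f"cyst {i}: target volume below one voxel volume")
        d_center, j = tree.query(np.asarray(cyst.center_mm))
        r_tube = float(_radius_profile(spec, np.array([arcs[j] / total_len]))[0])
        if d_center > r_tube:
            raise PlacementError(f"cyst {i}: center lies outside the pancreas tube")
        ratio = np.asarray(cyst.axes_ratio, dtype=float)
        r_eq = sphere_radius_for_volume(cyst.target_volume_mm3) / float(np.prod(ratio)) ** (1 / 3)
        semi = r_eq * ratio
        if d_center + float(semi.max()) > r_tube + fit_tol:
            raise PlacementError(
                f"cyst {i}: radius {semi.max():.2f} mm does not fit inside tube "
                f"(local radius {r_tube:.2f} mm at offset {d_center:.2f} mm)"
            )
        ids = _ellipsoid_voxels(cyst.center_mm, semi, shape, spacing, origin)
        if ids.size == 0:
            raise PlacementError(f"cyst {i}: voxelization is empty")
        if np.any(inst_flat[ids] != 0):
            raise PlacementError(f"cyst {i}: overlaps a previously placed cyst")
        inst_flat[ids] = i
        coords = np.stack(np.unravel_index(ids, shape), axis=1)
        centroid = np.asarray(origin) + coords.mean(axis=0) * np.asarray(spacing)
        rows.append(
            {
                "id": i,
                "volume_mm3": ids.size * vox_vol,
                "cx_mm": centroid[0],
                "cy_mm": centroid[1],
                "cz_mm": centroid[2],
                "hu": cyst.hu,
            }
        )

    # render HU
    ct = np.full(shape, spec.background_hu, dtype=np.float32)
    ct[pancreas] = spec.parenchyma_hu
    ct[duct] = spec.duct_hu
    cyst_any = instances > 0
    for i, cyst in enumerate(spec.cysts, start=1):
        ct[instances == i] = cyst.hu
    # truth duct excludes voxels swallowed by cysts so duct voxels keep duct HU
    duct &= ~cyst_any

    pancreas_flat = pancreas.ravel()
    for m, conf in enumerate(spec.confounders, start=1):
        r = sphere_radius_for_volume(conf.volume_mm3)
        d_center, j = tree.query(np.asarray(conf.center_mm))
        r_tube = float(_radius_profile(spec, np.array([arcs[j] / total_len]))[0])
        if d_center <= r_tube:
            raise PlacementError(f"confounder {m}: center lies inside the pancreas tube")
        if conf.kind == "tube":
            semi = (r / 2.0, r / 2.0, 2.0 * r)  # duct-like elongated structure
        else:
            semi = (r, r, r)
        ids = _ellipsoid_voxels(conf.center_mm, semi, shape, spacing, origin)
        ct.ravel()[ids] = conf.hu

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, size=shape).astype(np.float32)

    volume = VolumeImage(voxels=ct, spacing=spacing, origin=origin)
    truth = PhantomTruth(
        cyst_instances=LabelMask(instances, spacing, origin, semantics="cyst_instance"),
        duct_mask=LabelMask(duct, spacing, origin, semantics="duct"),
        pancreas_mask=LabelMask(pancreas, spacing, origin, semantics="pancreas"),
        catalogue=pd.DataFrame(rows, columns=["id", "volume_mm3", "cx_mm", "cy_mm", "cz_mm", "hu"]),
        seed=spec.seed,
    )
    return volume, truth


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A C-shaped pancreas in a 144×144×48 grid at (0.8, 0.8, 1.5) mm spacing.

    The tube tapers from 13 mm (head, patient right = large x) to 9 mm
    (tail); the curve is ~108 mm long, comparable to a human pancreas.
    """
    curve = [
        (100.0, 30.0, 30.0),
        (87.0, 45.0, 32.0),
        (68.0, 55.0, 35.0),
        (46.0, 56.0, 37.0),
        (27.0, 45.0, 40.0),
        (14.0, 27.0, 42.0),
    ]
    spec = PhantomSpec(
        grid_shape=(144, 144, 48),
        spacing=(0.8, 0.8, 1.5),
        pancreas_curve=curve,
        pancreas_radius_mm=(13.0, 9.0),
        seed=seed,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec


def place_volume_groups(
    n_per_group: tuple[int, int, int, int],
    spec_base: PhantomSpec,
    seed: int,
    cyst_hu: float = 10.0,
) -> PhantomSpec:
    """Return a spec with cysts stratified into the four volume groups.

    Target volumes are drawn uniformly within each group interval
    ([10,50], (50,200], (200,600], (600, 5000] mm³); centers are spread
    along the tube centerline, largest first (so big cysts sit where the
    tapering tube is widest), with clearance so no two cysts touch.
    """
    if len(n_per_group) != 4 or any(n < 0 for n in n_per_group):
        raise ValidationError("n_per_group must be four non-negative counts")
    rng = np.random.default_rng(seed)
    edges = list(GROUP_EDGES_MM3) + [GROUP_UPPER_CAP_MM3]
    volumes = []
    for g, n in enumerate(n_per_group):
        volumes.extend(rng.uniform(edges[g], edges[g + 1], size=n).tolist())
    if not volumes:
        return dataclasses.replace(spec_base, cysts=[])
    return place_cysts(volumes, dataclasses.replace(spec_base, seed=seed), cyst_hu=cyst_hu)


def place_cysts(volumes_mm3: Sequence[float], spec_base: PhantomSpec, cyst_hu: float = 10.0) -> PhantomSpec:
    """Deterministically place cysts of the given target volumes on the centerline.

    Cysts are sorted largest-first and spread along the tube from the
    proximal end (where a tapering tube is widest), with enough clearance
    that no two voxelized cysts touch under 26-connectivity.
    """
    step = min(spec_base.spacing) / 2.0
    curve = densify_polyline(spec_base.pancreas_curve, step)
    arcs = polyline_arclengths(curve)
    total = arcs[-1]
    clearance = 2.0 * max(spec_base.spacing)

    volumes = sorted(volumes_mm3, reverse=True)  # big cysts first, near the (wider) proximal end
    cysts: list[CystSpec] = []
    cursor = 0.0
    prev_r = 0.0
    for vol in volumes:
        r = sphere_radius_for_volume(vol)
        s = max(cursor + prev_r + r + clearance, r + clearance) if cysts else r + clearance
        # the tube only narrows distally, so an immediate width check fails fast
        r_here = float(_radius_profile(spec_base, np.array([min(s, total) / total]))[0])
        if r > r_here or s + r + clearance > total:
            raise PlacementError(
                f"tube too small for requested cyst load (volume {vol:.0f} mm³ "
                f"needs radius {r:.1f} mm at arc length {s:.1f} mm)"
            )
        j = min(int(np.searchsorted(arcs, s)), len(curve) - 1)
        cysts.append(CystSpec(target_volume_mm3=vol, center_mm=tuple(curve[j]), hu=cyst_hu))
        cursor, prev_r = s, r
    return dataclasses.replace(spec_base, cysts=cysts)


def simulate_detector_output(
    truth: PhantomTruth,
    drop_below_mm3: float = np.inf,
    drop_prob: float = 0.0,
    n_fp: int = 0,
    fp_volume_range_mm3: tuple[float, float] = (20.0, 150.0),
    seed: int = 0,
) -> LabelMask:
    """Ground truth plus known corruption, as a synthetic detector output.

    Each GT cyst below ``drop_below_mm3`` is omitted with probability
    ``drop_prob``; ``n_fp`` spurious spheres (disjoint from every GT cyst)
    are added inside the pancreas. Used for parameter-recovery checks: the
    pipeline must read back sensitivity ``1 − drop_prob`` in the affected
    volume range and ``n_fp`` false positives per case.
    """
    rng = np.random.default_rng(seed)
    inst = truth.cyst_instances.labels
    spacing = truth.cyst_instances.spacing
    origin = truth.cyst_instances.origin
    shape = inst.shape
    pred = np.zeros(shape, dtype=bool)
    for _, row in truth.catalogue.iterrows():
        keep = True
        if row["volume_mm3"] < drop_below_mm3:
            keep = rng.random() >= drop_prob
        if keep:
            pred |= inst == int(row["id"])

    cyst_any = inst > 0
    pancreas = truth.pancreas_mask.labels > 0
    candidates = np.argwhere(pancreas & ~cyst_any)
    pred_flat = pred.ravel()
    placed = 0
    attempts = 0
    while placed < n_fp and attempts < 500:
        attempts += 1
        c_idx = candidates[rng.integers(len(candidates))]
        center = np.asarray(origin) + c_idx * np.asarray(spacing)
        vol = rng.uniform(*fp_volume_range_mm3)
        r = sphere_radius_for_volume(vol)
        ids = _ellipsoid_voxels(center, (r, r, r), shape, spacing, origin)
        if ids.size * float(np.prod(spacing)) < 10.0:
            continue
        coords = np.stack(np.unravel_index(ids, shape), axis=1)
        # keep clear of GT cysts and of already-placed predictions (no merging)
        lo = np.maximum(coords.min(axis=0) - 2, 0)
        hi = np.minimum(coords.max(axis=0) + 3, shape)
        box = tuple(slice(lo[k], hi[k]) for k in range(3))
        if cyst_any[box].any() or pred[box].any():
            continue
        pred_flat[ids] = True
        placed += 1
    if placed < n_fp:
        raise PlacementError(f"could only place {placed} of {n_fp} false-positive blobs")
    return LabelMask(pred, spacing, origin, semantics="cyst_semantic")
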