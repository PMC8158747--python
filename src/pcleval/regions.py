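"""Equal-volume partition of the pancreas along its centerline.

The parenchyma is split into proximal/middle/distal thirds — proxies for
head+uncinate, body and tail — by (1) extracting a centerline from the 3D
skeleton of the mask, (2) assigning every pancreas voxel the arc length of
its nearest centerline point, and (3) cutting at the two arc lengths whose
cumulative voxel volume is closest to 1/3 and 2/3 of the total. Lesions are
attributed to the region holding the plurality of their voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .errors import DegenerateGeometryError, ValidationError
from .imaging import LabelMask
from .instances import STRUCT_26, LesionInstance

REGION_NAMES = {1: "proximal", 2: "middle", 3: "distal"}


@dataclass
class RegionMap:
    """Proximal(1)/middle(2)/distal(3) labels on the pancreas voxels."""

    region_labels: LabelMask
    centerline: np.ndarray  # (N, 3) world mm, ordered proximal → distal
    cut_arclengths: tuple[float, float]

    def region_volumes_mm3(self) -> dict[int, float]:
        vox = self.region_labels.voxel_volume
        counts = np.bincount(self.region_labels.labels.ravel(), minlength=4)
        return {k: float(counts[k] * vox) for k in (1, 2, 3)}


def _skeleton_longest_path(skel: np.ndarray, spacing) -> np.ndarray:
    """Longest geodesic path (voxel coords) through a 26-connected skeleton."""
    coords = np.argwhere(skel)
    n = len(coords)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    rows, cols, wts = [], [], []
    sp = np.asarray(spacing)
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < skel.shape), axis=1)
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = index[tuple(nb[ok].T)]
        hit = j >= 0
        rows.append(np.arange(n)[hit])
        cols.append(j[hit])
        wts.append(np.full(hit.sum(), np.linalg.norm(np.asarray(off) * sp)))
    rows, cols, wts = np.concatenate(rows), np.concatenate(cols), np.concatenate(wts)
    graph = coo_matrix((wts, (rows, cols)), shape=(n, n))
    graph = graph + graph.T

    # double sweep: farthest node from an arbitrary start, then farthest from it
    d0 = dijkstra(graph, indices=0, directed=False)
    a = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    da, pred = dijkstra(graph, indices=a, directed=False, return_predecessors=True)
    b = int(np.nanargmax(np.where(np.isinf(da), np.nan, da)))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return coords[path[::-1]]


def _smooth_polyline(poly: np.ndarray, window: int = 5) -> np.ndarray:
    if len(poly) < window:
        return poly
    pad = window // 2
    padded = np.pad(poly, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.stack([np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)], axis=1)


def _extend_to_mask_ends(poly: np.ndarray, mask: LabelMask) -> np.ndarray:
    """Extrapolate both ends along the local tangent while still inside the mask.

    Skeletonization retracts from the blunt ends of a tube by roughly one
    tube radius; extending the polyline restores full arc-length coverage.
    """
    labels = mask.labels
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    step = float(min(spacing))

    def inside(p):
        idx = np.rint((p - origin) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(labels.shape)):
            return False
        return labels[tuple(idx)] > 0

    def extend(end, tangent):
        t = tangent / (np.linalg.norm(tangent) + 1e-12)
        out = []
        p = end.copy()
        for _ in range(1000):
            p = p + t * step
            if not inside(p):
                break
            out.append(p.copy())
        return out

    k = min(5, len(poly) - 1)
    head = extend(poly[0], poly[0] - poly[k])
    tail = extend(poly[-1], poly[-1] - poly[-1 - k])
    parts = []
    if head:
        parts.append(np.asarray(head[::-1]))
    parts.append(poly)
    if tail:
        parts.append(np.asarray(tail))
    return np.vstack(parts)


def extract_centerline(pancreas: LabelMask, proximal_end: str = "right") -> np.ndarray:
    """Ordered world-mm centerline of the pancreas mask, proximal → distal.

    The mask is skeletonized in 3D; the longest geodesic path through the
    skeleton is smoothed (moving average, window 5) and extended to the mask
    ends. ``proximal_end`` orients the polyline: ``"right"`` (default) puts
    the endpoint with the larger RAS x first — the pancreatic head lies to
    the patient's right — ``"left"`` the opposite, ``"as-is"`` keeps the
    skeleton order.
    """
    mask = pancreas.labels > 0
    if not mask.any():
        raise DegenerateGeometryError("pancreas mask is empty")
    labeled, n = ndimage.label(mask, structure=STRUCT_26)
    if n > 1:
        warnings.warn(f"pancreas mask has {n} components; using the largest", stacklevel=2)
        counts = np.bincount(labeled.ravel())
        counts[0] = 0
        mask = labeled == int(np.argmax(counts))

    skel = skeletonize(mask)
    if skel.sum() < 3:
        raise DegenerateGeometryError("mask too thin for centerline extraction")
    path_vox = _skeleton_longest_path(skel, pancreas.spacing)
    if len(path_vox) < 3:
        raise DegenerateGeometryError("skeleton longest path is degenerate")

    poly = pancreas.voxel_centers(path_vox)
    poly = _smooth_polyline(poly, window=5)
    poly = _extend_to_mask_ends(poly, pancreas)

    if proximal_end == "right":
        if poly[0, 0] < poly[-1, 0]:
            poly = poly[::-1]
    elif proximal_end == "left":
        if poly[0, 0] > poly[-1, 0]:
            poly = poly[::-1]
    elif proximal_end != "as-is":
        raise ValidationError("proximal_end must be 'right', 'left' or 'as-is'")
    return poly


def polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _voxel_arclengths(points_mm: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    arcs = polyline_arclengths(centerline)
    _, nearest = cKDTree(centerline).query(points_mm, workers=-1)
    return arcs[nearest]


def partition_equal_volumes(pancreas: LabelMask, centerline: np.ndarray) -> RegionMap:
    """Cut the pancreas into three equal-volume regions along the centerline."""
    if centerline is None or len(centerline) < 3:
        raise ValidationError("centerline must have at least 3 points")
    coords = np.argwhere(pancreas.labels > 0)
    if coords.size == 0:
        raise DegenerateGeometryError("pancreas mask is empty")
    s = _voxel_arclengths(pancreas.voxel_centers(coords), centerline)
    n = len(s)

    uniq, counts = np.unique(s, return_counts=True)
    cum = np.cumsum(counts)
    c1 = float(uniq[np.argmin(np.abs(cum - n / 3.0))])
    # second cut chosen among values >= c1 so labels stay ordered
    valid = uniq >= c1
    c2 = float(uniq[valid][np.argmin(np.abs(cum[valid] - 2.0 * n / 3.0))])

    labels_on_vox = np.where(s <= c1, 1, np.where(s <= c2, 2, 3))
    out = np.zeros(pancreas.shape, dtype=np.int32)
    out[tuple(coords.T)] = labels_on_vox
    region_mask = LabelMask(out, pancreas.spacing, pancreas.origin, semantics="region")
    return RegionMap(region_labels=region_mask, centerline=np.asarray(centerline), cut_arclengths=(c1, c2))


def assign_lesion_region(lesion: LesionInstance, regions: RegionMap) -> int:
    """Region (1/2/3) holding the plurality of the lesion's voxels.

    Lesion voxels outside the parenchyma (exophytic parts) are mapped to the
    region of their nearest centerline arc length. Plurality ties break
    toward the more proximal region.
    """
    if not lesion.voxel_ids:
        raise ValidationError("lesion has an empty voxel set")
    mask = regions.region_labels
    flat = mask.labels.ravel()
    ids = np.fromiter(lesion.voxel_ids, dtype=np.int64)
    lab = flat[ids].astype(np.int64)

    outside = lab == 0
    if outside.any():
        coords = np.stack(np.unravel_index(ids[outside], mask.shape), axis=1)
        s = _voxel_arclengths(mask.voxel_centers(coords), regions.centerline)
        c1, c2 = regions.cut_arclengths
        lab[outside] = np.where(s <= c1, 1, np.where(s <= c2, 2, 3))

    counts = np.bincount(lab, minlength=4)[1:4]
    return int(np.argmax(counts)) + 1  # argmax takes the first (most proximal) on ties
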