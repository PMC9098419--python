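"""Validation metrics: tissue contrast, slice-weighted Dice, and the
radius-matched signed surface distance on the perimeter-reduced
cartilage-adjacent region.

Contrast between bone and cartilage is ``|I_bone - I_cart| / I_cart``.
Dice overlap is computed per slice on filled contour interiors and averaged
with weights equal to the number of segmented pixels in the slice.  The
surface distance between two registered bone meshes matches each analyzed
vertex of model A to the average of all model-B vertices within a search
radius (default 2.5 mm) and reports the signed difference of x-coordinates
(x being perpendicular to the articular face): positive distances mean
model A is locally larger.  To avoid edge effects, the analyzed
cartilage-adjacent region is first shrunk by a perimeter reduction
(default 25%) of its projected boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.affinity import scale as shapely_scale
from shapely.geometry import MultiPoint, Point

from .model_building import SurfaceMesh

DEFAULT_MATCH_RADIUS_MM = 2.5
DEFAULT_PERIMETER_REDUCTION = 0.25


@dataclass
class ContrastValue:
    intensity_bone: float
    intensity_cartilage: float
    contrast: float


@dataclass
class DiceReport:
    """Per-slice Dice coefficients with pixel-count weights."""

    per_slice: list[tuple[int, int, int, int, float]]  # (slice, |X∩Y|, |X|, |Y|, dsc)
    weights: list[int]
    weighted_mean: float


@dataclass
class SurfaceDistanceReport:
    """Signed distances between matched vertices of two registered meshes."""

    vertex_indices: np.ndarray       # model-A vertex index per matched vertex
    matched_points: np.ndarray       # averaged model-B match per vertex, mm
    distances_mm: np.ndarray         # signed x-differences, mm
    unmatched_count: int
    mean_mm: float
    sd_mm: float
    region: str = "perimeter_reduced"

    @property
    def matched_count(self) -> int:
        return len(self.distances_mm)


def compute_contrast(intensity_bone: float, intensity_cartilage: float) -> ContrastValue:
    """Bone/cartilage contrast ``|I_bone - I_cart| / I_cart``."""
    if intensity_cartilage == 0:
        raise ValueError("cartilage intensity must be nonzero")
    contrast = abs((intensity_bone - intensity_cartilage) / intensity_cartilage)
    return ContrastValue(float(intensity_bone), float(intensity_cartilage), float(contrast))


def dice(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Dice similarity coefficient ``2|X∩Y| / (|X| + |Y|)``; 1.0 when both
    masks are empty."""
    x = np.asarray(mask_x, dtype=bool)
    y = np.asarray(mask_y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def weighted_dice(masks_a: "dict[int, np.ndarray] | np.ndarray",
                  masks_b: "dict[int, np.ndarray] | np.ndarray") -> DiceReport:
    """Slice-weighted Dice over two segmentations' filled per-slice masks.

    Accepts per-slice mask dicts (slice index -> 2D bool grid) or aligned 3D
    binary volumes.  Only slices with segmented pixels in either input
    contribute; the weight of slice ``s`` is ``|X_s| + |Y_s|``, which keeps
    the aggregate symmetric in the two segmentations.
    """
    def as_dict(m):
        if isinstance(m, dict):
            return {int(k): np.asarray(v, dtype=bool) for k, v in m.items()}
        arr = np.asarray(m, dtype=bool)
        return {k: arr[k] for k in range(arr.shape[0])}

    da, db = as_dict(masks_a), as_dict(masks_b)
    slices = sorted(set(da) | set(db))
    per_slice = []
    weights = []
    for k in slices:
        shape = da[k].shape if k in da else db[k].shape
        x = da.get(k, np.zeros(shape, dtype=bool))
        y = db.get(k, np.zeros(shape, dtype=bool))
        nx, ny = int(x.sum()), int(y.sum())
        if nx + ny == 0:
            continue
        inter = int((x & y).sum())
        per_slice.append((k, inter, nx, ny, 2.0 * inter / (nx + ny)))
        weights.append(nx + ny)
    if not per_slice:
        raise ValueError("no slices contain segmented pixels")
    num = sum(w * row[4] for w, row in zip(weights, per_slice))
    return DiceReport(per_slice=per_slice, weights=weights,
                      weighted_mean=num / sum(weights))


def perimeter_reduce(mesh: SurfaceMesh, fraction: float,
                     flags: np.ndarray | None = None) -> np.ndarray:
    """Shrink the flagged region's boundary inward by a perimeter fraction.

    Flagged vertices are projected onto the y–z plane (perpendicular to the
    x axis); the region's boundary polygon (convex hull of the projections)
    is scaled about its area centroid by ``1 - fraction``, and only vertices
    whose projection falls inside the scaled polygon stay flagged.  For a
    circular region this reduces the boundary perimeter by exactly the given
    fraction.
    """
    if flags is None:
        flags = mesh.cartilage_face_flags
    if flags is None or not np.any(flags):
        raise ValueError("mesh has no flagged cartilage-adjacent region")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    flags = np.asarray(flags, dtype=bool)
    if fraction == 0:
        return flags.copy()
    proj = mesh.vertices[flags][:, 1:3]
    hull = MultiPoint(proj).convex_hull
    if hull.area == 0:  # degenerate (collinear) region: nothing survives
        return np.zeros_like(flags)
    c = hull.centroid
    shrunk = shapely_scale(hull, xfact=1.0 - fraction, yfact=1.0 - fraction,
                           origin=(c.x, c.y))
    keep = np.zeros_like(flags)
    idx = np.nonzero(flags)[0]
    for i, (py, pz) in zip(idx, proj):
        if shrunk.covers(Point(py, pz)):
            keep[i] = True
    return keep


def surface_distance(model_a: SurfaceMesh, model_b: SurfaceMesh,
                     radius_mm: float = DEFAULT_MATCH_RADIUS_MM,
                     fraction: float = DEFAULT_PERIMETER_REDUCTION) -> SurfaceDistanceReport:
    """Signed x-distance between matched vertices of two registered meshes.

    Both meshes are first centered by subtracting model A's vertex-mean
    centroid.  Each model-A vertex surviving the perimeter reduction of the
    cartilage-adjacent region gathers all model-B vertices within
    ``radius_mm``, averaged to the matched vertex ``q``; model A's own
    vertices within the same radius are averaged likewise, and the signed
    distance is the difference of the two patch means' x-coordinates
    (positive where model A is locally larger, the articular face pointing
    toward +x).  Using A's local patch mean rather than the raw vertex
    cancels the inward bias both averages share on curved surfaces, so
    identical meshes yield exactly zero.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if model_a.cartilage_face_flags is None:
        raise ValueError("model_a must carry cartilage_face_flags")
    centroid = model_a.vertices.mean(axis=0)
    va = model_a.vertices - centroid
    vb = model_b.vertices - centroid
    keep = perimeter_reduce(model_a, fraction)
    region = "perimeter_reduced" if fraction > 0 else "whole_cartilage_region"
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        raise ValueError("no vertices survive the perimeter reduction")
    tree_b = cKDTree(vb)
    tree_a = cKDTree(va)
    neighbors_b = tree_b.query_ball_point(va[idx], r=radius_mm)
    neighbors_a = tree_a.query_ball_point(va[idx], r=radius_mm)
    v_idx, matched, dists = [], [], []
    unmatched = 0
    for i, nbrs_a, nbrs_b in zip(idx, neighbors_a, neighbors_b):
        if not nbrs_b:
            unmatched += 1
            continue
        q = vb[nbrs_b].mean(axis=0)
        # x-means computed with identical 1D reductions so that comparing a
        # mesh with itself yields exactly zero
        p_x = va[nbrs_a, 0].mean()
        q_x = vb[nbrs_b, 0].mean()
        v_idx.append(i)
        matched.append(q)
        dists.append(p_x - q_x)
    if not dists:
        raise ValueError("no model-A vertex matched any model-B vertex within the radius")
    dists = np.asarray(dists)
    sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    return SurfaceDistanceReport(
        vertex_indices=np.asarray(v_idx, dtype=int),
        matched_points=np.asarray(matched),
        distances_mm=dists,
        unmatched_count=unmatched,
        mean_mm=float(np.mean(dists)),
        sd_mm=sd,
        region=region,
    )
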