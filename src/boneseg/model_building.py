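"""From per-slice boundaries to 3D point clouds and closed surface meshes.

The meshing route is deliberate: ordered slice contours are rasterized to
filled binary masks, stacked into a binary volume, and the bone surface is
extracted with marching cubes at the 0.5 level in mm coordinates, followed
by uniform Laplacian smoothing.  The same post-processing is applied to
every mesh that enters a comparison, so systematic smoothing effects cancel
in the signed surface distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .boundary_tracking import BoundarySet, Pixel, connected_components_8
from .phantom import GroundTruth
from .volume_io import ImageVolume, voxels_to_mm

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_ITERS = 10
SMOOTH_FACTOR = 0.5
DEFAULT_ADJACENCY_RADIUS_MM = 1.0

#: Gaussian pre-smoothing (voxels) of the stacked binary masks before
#: isosurface extraction
PRE_MESH_FIELD_SIGMA = 0.7


@dataclass
class PointCloud3D:
    """N points in mm with provenance metadata."""

    points: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("points must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def save_xyz(self, path: str | Path) -> None:
        np.savetxt(path, self.points, fmt="%.6f")

    def save_ply(self, path: str | Path) -> None:
        trimesh.PointCloud(self.points).export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "PointCloud3D":
        path = Path(path)
        if path.suffix == ".xyz" or path.suffix == ".txt":
            return cls(np.loadtxt(path, ndmin=2))
        loaded = trimesh.load(str(path))
        if isinstance(loaded, trimesh.points.PointCloud):
            return cls(np.asarray(loaded.vertices))
        return cls(np.asarray(loaded.vertices))


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm with optional cartilage-adjacency flags."""

    vertices: np.ndarray
    faces: np.ndarray
    cartilage_face_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face indices out of range")
        if np.any(self.faces[:, 0] == self.faces[:, 1]) \
                or np.any(self.faces[:, 1] == self.faces[:, 2]) \
                or np.any(self.faces[:, 0] == self.faces[:, 2]):
            raise ValueError("degenerate face with repeated vertex")
        if self.cartilage_face_flags is not None:
            self.cartilage_face_flags = np.asarray(self.cartilage_face_flags, dtype=bool)
            if self.cartilage_face_flags.shape != (len(self.vertices),):
                raise ValueError("cartilage_face_flags must be per-vertex")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(),
                               process=False)

    def is_closed(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def save_ply(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))

    @classmethod
    def load_ply(cls, path: str | Path) -> "SurfaceMesh":
        m = trimesh.load(str(path), process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


def boundary_to_pointcloud(boundary: BoundarySet, volume: ImageVolume,
                           provenance: dict | None = None) -> PointCloud3D:
    """One mm point per boundary pixel."""
    idx = [(k, r, c) for k, pix in sorted(boundary.boundary.items()) for r, c in sorted(pix)]
    if not idx:
        raise ValueError("boundary set is empty")
    pts = voxels_to_mm(volume, np.asarray(idx))
    prov = dict(provenance or {})
    prov.setdefault("n_slices", len(boundary.nonempty_slices()))
    return PointCloud3D(pts, prov)


def _greedy_order(pixels: "set[Pixel] | list[Pixel]") -> np.ndarray:
    """Greedy nearest-unvisited-neighbour traversal from the smallest
    (row, col) pixel, closed back to the start."""
    remaining = sorted(set(map(tuple, pixels)))
    ordered = [remaining.pop(0)]
    pts = np.asarray(remaining, dtype=float)
    alive = np.ones(len(remaining), dtype=bool)
    current = np.asarray(ordered[0], dtype=float)
    while alive.any():
        d2 = np.sum((pts - current) ** 2, axis=1)
        d2[~alive] = np.inf
        i = int(np.argmin(d2))
        alive[i] = False
        ordered.append(remaining[i])
        current = pts[i]
    return np.asarray(ordered, dtype=int)


def order_contour(pixels: set[Pixel] | list[Pixel]) -> np.ndarray:
    """Order a ring-like 8-connected pixel set into a closed polygon.

    Traversal is greedy nearest-unvisited-neighbour starting from the
    smallest (row, col) pixel; the polygon closes back to the start.  A
    multi-component input is an error; a self-crossing result only warns.
    """
    comps = connected_components_8(pixels)
    if len(comps) != 1:
        raise ValueError(f"contour must be a single 8-connected component, got {len(comps)}")
    poly = _greedy_order(comps[0])
    if len(poly) >= 4:
        try:
            from shapely.geometry import LinearRing

            if not LinearRing(poly.astype(float)).is_simple:
                logger.warning("ordered contour is self-crossing; proceeding")
        except Exception:  # degenerate (collinear) rings
            pass
    return poly


#: contour pixels propagated slice-to-slice carry 1-2 px sampling gaps;
#: fragments this close are treated as one ring when rasterizing
FILL_MAX_GAP_PX = 4.0


def _fill_contour(pixels: set[Pixel], shape: tuple[int, int],
                  max_gap_px: float = FILL_MAX_GAP_PX) -> np.ndarray:
    """Rasterize a (possibly fragmented, possibly noisy) boundary ring to a
    filled mask.

    Boundary pixels propagated slice to slice carry small sampling gaps and
    occasional near-ring strays, so instead of tracing a polygon the ring is
    bridged by a morphological closing (disk radius ``max_gap_px / 2``) and
    its interior filled; the original boundary pixels are kept in the mask.
    """
    arr = np.array(sorted(set(map(tuple, pixels))), dtype=int)
    if len(arr) == 0:
        raise ValueError("empty contour")
    grid = np.zeros(shape, dtype=bool)
    grid[arr[:, 0], arr[:, 1]] = True
    try:
        from scipy.spatial import ConvexHull

        hull_area = float(ConvexHull(arr).volume)  # 2D hull "volume" is area
    except Exception:  # degenerate (collinear) rings
        hull_area = 0.0
    base = max(1, int(round(max_gap_px / 2)))
    best = grid
    for radius in range(base, base + 3):
        selem = morphology.disk(radius)
        # dilate -> fill -> erode: bridges ring gaps up to ~2*radius while
        # the erosion puts the filled region's boundary back on the ring
        thick = ndimage.binary_dilation(grid, structure=selem)
        filled = ndimage.binary_fill_holes(thick)
        mask = ndimage.binary_erosion(filled, structure=selem) | grid
        if mask.sum() > best.sum():
            best = mask
        # a successful fill covers most of the ring's convex hull; a thin
        # unclosed ring does not, so widen the bridge and retry
        if hull_area == 0.0 or mask.sum() >= 0.6 * hull_area:
            return mask
    logger.warning("contour fill covers only %d px of ~%.0f px hull area; "
                   "ring may be unclosed", int(best.sum()), hull_area)
    return best


def boundary_masks(boundary: BoundarySet, shape_2d: tuple[int, int]) -> dict[int, np.ndarray]:
    """Filled per-slice masks for every non-empty boundary slice."""
    out = {}
    for k in boundary.nonempty_slices():
        try:
            out[k] = _fill_contour(boundary.boundary[k], shape_2d)
        except ValueError as exc:
            raise ValueError(f"slice {k}: {exc}") from exc
    return out


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int,
                      factor: float = SMOOTH_FACTOR) -> np.ndarray:
    """Uniform (umbrella) Laplacian smoothing: v <- v + factor*(mean(nbrs)-v)."""
    if iterations <= 0:
        return vertices
    n = len(vertices)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    ii = np.concatenate([edges[:, 0], edges[:, 1]])
    jj = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0  # deduplicate repeated edges
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(iterations):
        v = v + factor * (adj @ v / deg[:, None] - v)
    return v


def build_mesh(boundary: BoundarySet, volume: ImageVolume,
               smoothing_iters: int = DEFAULT_SMOOTH_ITERS) -> SurfaceMesh:
    """Rasterize slice contours to filled masks, stack, extract the 0.5
    isosurface with marching cubes in mm coordinates, and smooth.

    The resulting surface is closed (verified); an unorderable slice raises
    a validation error naming the slice.
    """
    slices = boundary.nonempty_slices()
    if len(slices) < 3:
        raise ValueError("need at least 3 slices with non-empty boundaries")
    ns, nr, nc = volume.shape
    masks = boundary_masks(boundary, (nr, nc))
    s0, s1 = min(masks), max(masks)
    grid = np.zeros((s1 - s0 + 1, nr, nc), dtype=float)
    for k, m in masks.items():
        grid[k - s0] = m
    pad = 3
    padded = np.pad(grid, pad)
    # a mild Gaussian on the binary field removes the voxel staircase (and
    # with it marching-cubes pinch points at diagonally-touching pixels);
    # the 0.5 level stays centred on the original boundary
    field = ndimage.gaussian_filter(padded, PRE_MESH_FIELD_SIGMA)
    ds, dr, dc = volume.spacing
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=(ds, dr, dc))
    # padded array axes are (slice, row, col); shift back to volume indices
    x0, y0, z0 = volume.origin
    z = z0 + (s0 - pad) * ds + verts[:, 0]
    x = x0 - pad * dr + verts[:, 1]
    y = y0 - pad * dc + verts[:, 2]
    vertices = np.column_stack([x, y, z])
    vertices = _laplacian_smooth(vertices, faces, smoothing_iters)
    mesh = SurfaceMesh(vertices, faces)
    if not mesh.is_closed():
        raise RuntimeError("extracted surface is not closed")
    return mesh


def flag_cartilage_region(mesh: SurfaceMesh,
                          cartilage: "GroundTruth | PointCloud3D | np.ndarray",
                          adjacency_radius_mm: float = DEFAULT_ADJACENCY_RADIUS_MM,
                          volume: ImageVolume | None = None) -> SurfaceMesh:
    """Flag mesh vertices within ``adjacency_radius_mm`` of cartilage.

    ``cartilage`` may be a ground-truth mask set (then ``volume`` supplies
    the voxel-to-mm mapping), a point cloud, or a raw (N, 3) mm array.
    Returns a new mesh with ``cartilage_face_flags`` populated.
    """
    if adjacency_radius_mm <= 0:
        raise ValueError("adjacency_radius_mm must be positive")
    if isinstance(cartilage, GroundTruth):
        if volume is None:
            raise ValueError("volume required to locate ground-truth cartilage voxels in mm")
        idx = np.argwhere(cartilage.cartilage_mask)
        if len(idx) == 0:
            raise ValueError("cartilage mask is empty")
        pts = voxels_to_mm(volume, idx)
    elif isinstance(cartilage, PointCloud3D):
        pts = cartilage.points
    else:
        pts = np.asarray(cartilage, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("cartilage input must be a non-empty (N, 3) array")
    tree = cKDTree(pts)
    d, _ = tree.query(mesh.vertices, distance_upper_bound=adjacency_radius_mm)
    flags = np.isfinite(d)
    return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy(), flags)
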