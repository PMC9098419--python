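"""Seeded selection of bone-boundary edges and slice-to-slice propagation.

A user (here: a scripted edit list) initializes a handful of slices —
typically one in five — by removing a few pixels that 8-connect the bone
boundary to stray edges and then seeding the components to keep.  The
boundary is then propagated outward: each boundary pixel of a processed
slice pulls its nearest edge pixel (Euclidean pixel distance, capped by a
search radius) from the adjacent slice.  Fronts from different initialized
slices never overwrite each other; the nearest initializer wins.

``auto_seed_from_mask`` plays the human's role in tests and phantom
experiments, deriving seeds and removals from the ground-truth bone mask.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .edge_detection import EdgeMap
from .phantom import GroundTruth

logger = logging.getLogger(__name__)

Pixel = tuple[int, int]

_STRUCT8 = np.ones((3, 3), dtype=bool)

DEFAULT_RADIUS_PX = 3.0
DEFAULT_EVERY_N = 5


@dataclass
class EditScript:
    """Per-slice scripted edits standing in for interactive picking.

    ``seeds[k]`` are pixels identifying 8-connected edge components to keep
    on slice ``k``; ``remove[k]`` are pixels deleted first (to break
    connectivity with stray edges).  Slices listed with seeds are the
    initialized slices; removals may also target propagated slices
    (post-propagation cleanup).
    """

    seeds: dict[int, list[Pixel]] = field(default_factory=dict)
    remove: dict[int, list[Pixel]] = field(default_factory=dict)

    def seeded_slices(self) -> list[int]:
        return sorted(k for k, v in self.seeds.items() if v)

    def to_json(self) -> str:
        slices: dict[str, dict] = {}
        for k in sorted(set(self.seeds) | set(self.remove)):
            slices[str(k)] = {
                "seeds": [list(p) for p in self.seeds.get(k, [])],
                "remove": [list(p) for p in self.remove.get(k, [])],
            }
        return json.dumps({"slices": slices}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EditScript":
        payload = json.loads(text)
        seeds: dict[int, list[Pixel]] = {}
        remove: dict[int, list[Pixel]] = {}
        for key, entry in payload.get("slices", {}).items():
            k = int(key)
            if entry.get("seeds"):
                seeds[k] = [tuple(p) for p in entry["seeds"]]
            if entry.get("remove"):
                remove[k] = [tuple(p) for p in entry["remove"]]
        return cls(seeds=seeds, remove=remove)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EditScript":
        return cls.from_json(Path(path).read_text())


@dataclass
class BoundarySet:
    """The algorithm's evolving state: per-slice boundary pixel sets.

    ``boundary`` maps slice index to the set of (row, col) pixels currently
    designated as bone boundary; a slice key present with an empty set means
    the slice was processed but nothing was found.  ``edits`` logs applied
    script actions.
    """

    boundary: dict[int, set[Pixel]] = field(default_factory=dict)
    initialized_slices: set[int] = field(default_factory=set)
    edits: list[tuple[int, Pixel, str]] = field(default_factory=list)

    def nonempty_slices(self) -> list[int]:
        return sorted(k for k, v in self.boundary.items() if v)

    def total_pixels(self) -> int:
        return sum(len(v) for v in self.boundary.values())


def connected_components_8(pixels: set[Pixel] | list[Pixel]) -> list[set[Pixel]]:
    """Partition pixels into maximal 8-connected components.

    Components are ordered by their smallest (row, col) member, making the
    result deterministic for any input order.
    """
    pts = list(set(map(tuple, pixels)))
    if not pts:
        return []
    arr = np.array(pts, dtype=int)
    rmin, cmin = arr.min(axis=0)
    rmax, cmax = arr.max(axis=0)
    grid = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    grid[arr[:, 0] - rmin, arr[:, 1] - cmin] = True
    labels, count = ndimage.label(grid, structure=_STRUCT8)
    comps: dict[int, set[Pixel]] = {}
    rr, cc = np.nonzero(grid)
    for r, c in zip(rr.tolist(), cc.tolist()):
        comps.setdefault(int(labels[r, c]), set()).add((r + int(rmin), c + int(cmin)))
    return sorted(comps.values(), key=min)


def initialize_slice(edge_map: EdgeMap, slice_idx: int, script: EditScript) -> set[Pixel]:
    """Apply a slice's scripted removals and keep the seeded components.

    Returns the kept boundary pixel set (the slice's contribution to a
    :class:`BoundarySet`).  Raises if the script has no seeds for the slice
    or a seed does not land on a remaining edge pixel.
    """
    seeds = script.seeds.get(slice_idx, [])
    if not seeds:
        raise ValueError(f"no seeds scripted for slice {slice_idx}")
    pixels = edge_map.slice_pixels(slice_idx)
    for p in script.remove.get(slice_idx, []):
        pixels.discard(tuple(p))
    for s in seeds:
        if tuple(s) not in pixels:
            raise ValueError(f"seed pixel {tuple(s)} is not an edge pixel on slice {slice_idx}")
    kept: set[Pixel] = set()
    for comp in connected_components_8(pixels):
        if any(tuple(s) in comp for s in seeds):
            kept |= comp
    return kept


def _nearest_in_target(source: set[Pixel], target: set[Pixel], radius_px: float) -> set[Pixel]:
    """For each source pixel, its nearest target pixel within the radius;
    distance ties broken by smallest (row, col)."""
    if not source or not target:
        return set()
    tgt = sorted(target)  # sorted so index order equals (row, col) order
    tree = cKDTree(np.asarray(tgt, dtype=float))
    out: set[Pixel] = set()
    src = np.asarray(sorted(source), dtype=float)
    neighbor_lists = tree.query_ball_point(src, r=radius_px)
    for p, idxs in zip(src, neighbor_lists):
        if not idxs:
            continue
        best = min(idxs, key=lambda i: ((tgt[i][0] - p[0]) ** 2 + (tgt[i][1] - p[1]) ** 2, tgt[i]))
        out.add(tgt[best])
    return out


def propagate(edge_map: EdgeMap, boundary: BoundarySet,
              radius_px: float = DEFAULT_RADIUS_PX,
              script: EditScript | None = None,
              slice_range: tuple[int, int] | None = None) -> BoundarySet:
    """Propagate initialized boundaries outward through the slice stack.

    Slices are processed in order of distance from their nearest initialized
    slice (nearest initializer wins; at equal distance the lower initializer
    is used).  Each boundary pixel on the source slice pulls its nearest edge
    pixel within ``radius_px`` on the target slice.  If a target slice yields
    no pixels, it is recorded empty with a warning and propagation continues
    from the last non-empty slice.  Scripted ``remove`` entries for a slice
    are applied after assignment.  Already-assigned slices are never
    overwritten, which also makes repeated calls no-ops.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    inits = sorted(boundary.initialized_slices)
    if not inits:
        raise ValueError("at least one initialized slice is required")
    n_slices = edge_map.edges.shape[0]
    lo, hi = slice_range if slice_range is not None else (0, n_slices - 1)

    def nearest_init(k: int) -> int:
        return min(inits, key=lambda i: (abs(i - k), i))

    order = sorted((k for k in range(lo, hi + 1) if k not in boundary.boundary),
                   key=lambda k: (abs(nearest_init(k) - k), k))
    for k in order:
        init = nearest_init(k)
        step = 1 if k > init else -1
        # walk back toward the initializer for the last non-empty source
        src_idx = k - step
        while src_idx != init and not boundary.boundary.get(src_idx):
            src_idx -= step
        source = boundary.boundary.get(src_idx, set())
        target_pixels = edge_map.slice_pixels(k)
        if script is not None:
            for p in script.remove.get(k, []):
                if tuple(p) in target_pixels:
                    target_pixels.discard(tuple(p))
                    boundary.edits.append((k, tuple(p), "remove"))
        assigned = _nearest_in_target(source, target_pixels, radius_px)
        if not assigned:
            logger.warning("slice %d: no edge pixels within %.2f px of the source boundary",
                           k, radius_px)
        boundary.boundary[k] = assigned
    return boundary


def auto_seed_from_mask(edge_map: EdgeMap, truth: GroundTruth,
                        every_n: int = DEFAULT_EVERY_N, offset: int = 0,
                        dilate_px: int = 2,
                        dense_radius_px: float | None = None) -> EditScript:
    """Derive an edit script from ground truth (test-time stand-in for the
    human operator).

    Every ``every_n``-th slice intersecting the bone mask (starting at
    ``offset``) gets one seed per edge component overlapping the
    ``dilate_px``-dilated ground-truth bone boundary, plus removals cutting
    the 8-connections between those components and edges outside the band.

    With ``dense_radius_px`` set, slices whose bone cross-section shifts by
    more than that many pixels relative to an adjacent slice (equivalent
    circular radius) are seeded as well.  Near the poles of the bone the
    contour moves several pixels per slice — faster than any safe
    propagation radius — and a human operator initializes those images
    directly; this option emulates that.
    """
    if every_n < 1:
        raise ValueError("every_n must be >= 1")
    bone_slices = [int(k) for k in np.nonzero(truth.bone_mask.any(axis=(1, 2)))[0]]
    if not bone_slices:
        raise ValueError("ground truth contains no bone slices")
    chosen = set(bone_slices[offset % every_n::every_n])
    if dense_radius_px is not None:
        areas = truth.bone_mask[bone_slices].sum(axis=(1, 2))
        radii = np.sqrt(areas / np.pi)
        jumps = np.abs(np.diff(radii)) > dense_radius_px
        for i in np.nonzero(jumps)[0]:
            chosen.add(bone_slices[i])
            chosen.add(bone_slices[i + 1])
    chosen = sorted(chosen)
    script = EditScript()
    for k in chosen:
        mask = truth.bone_mask[k]
        boundary = mask & ~ndimage.binary_erosion(mask)
        band = ndimage.binary_dilation(boundary, structure=_STRUCT8, iterations=dilate_px)
        edges = edge_map.edges[k]
        inside = edges & band
        # bridge pixels: outside the band but 8-adjacent to an in-band edge
        bridges = edges & ~band & ndimage.binary_dilation(inside, structure=_STRUCT8)
        removals = [(int(r), int(c)) for r, c in zip(*np.nonzero(bridges))]
        remaining = edge_map.slice_pixels(k) - set(removals)
        band_set = {(int(r), int(c)) for r, c in zip(*np.nonzero(band))}
        seeds: list[Pixel] = []
        for comp in connected_components_8(remaining):
            if comp & band_set:
                seeds.append(min(comp))
        if not seeds:
            raise ValueError(
                f"slice {k}: no edge component overlaps the ground-truth bone boundary "
                "(threshold/phantom mismatch)")
        script.seeds[k] = seeds
        if removals:
            script.remove[k] = sorted(removals)
    return script


def run_segmentation(edge_map: EdgeMap, script: EditScript,
                     radius_px: float = DEFAULT_RADIUS_PX,
                     slice_range: tuple[int, int] | None = None) -> BoundarySet:
    """Initialize every seeded slice of the script, then propagate."""
    bset = BoundarySet()
    for k in script.seeded_slices():
        bset.boundary[k] = initialize_slice(edge_map, k, script)
        bset.initialized_slices.add(k)
    return propagate(edge_map, bset, radius_px=radius_px, script=script,
                     slice_range=slice_range)
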