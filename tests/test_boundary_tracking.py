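import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

from boneseg import connected_components_8, initialize_slice, propagate
from boneseg.boundary_tracking import (
    BoundarySet,
    EditScript,
    auto_seed_from_mask,
    run_segmentation,
)
from boneseg.edge_detection import EdgeMap, detect_edges
from boneseg.experiments import bone_crop_region, crop_truth
from boneseg.volume_io import crop


def edge_map_from_slices(slices, shape):
    edges = np.zeros((len(slices),) + shape, dtype=bool)
    for k, pixels in enumerate(slices):
        for r, c in pixels:
            edges[k, r, c] = True
    return EdgeMap(edges, high_threshold=0.5, low_threshold=0.2, sigma=1.0)


def union_find_components(pixels):
    """Brute-force 8-connectivity oracle over all pixel pairs."""
    pixels = sorted(set(pixels))
    parent = {p: p for p in pixels}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(pixels):
        for q in pixels[i + 1:]:
            if max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1:
                parent[find(p)] = find(q)
    groups = {}
    for p in pixels:
        groups.setdefault(find(p), set()).add(p)
    return sorted(groups.values(), key=min)


def circle_pixels(r0, c0, radius):
    rr, cc = draw.circle_perimeter(r0, c0, radius)
    return set(zip(rr.tolist(), cc.tolist()))


class TestConnectedComponents:
    def test_diagonal_counts_as_adjacent(self):
        assert len(connected_components_8({(0, 0), (1, 1)})) == 1

    def test_two_components(self):
        comps = connected_components_8({(0, 0), (0, 1), (5, 5)})
        assert [len(c) for c in comps] == [2, 1]

    def test_matches_union_find_on_random_sprinkles(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            pts = {(int(r), int(c)) for r, c in rng.integers(0, 50, size=(200, 2))}
            assert connected_components_8(pts) == union_find_components(pts)

    def test_empty_input(self):
        assert connected_components_8(set()) == []


class TestInitializeSlice:
    def test_seed_keeps_only_its_component(self):
        circle = circle_pixels(30, 30, 15)
        blob = {(5, 5), (5, 6), (6, 5)}
        emap = edge_map_from_slices([circle | blob], (64, 64))
        script = EditScript(seeds={0: [min(circle)]})
        assert initialize_slice(emap, 0, script) == circle

    def test_removal_breaks_bridge_to_spur(self):
        circle = circle_pixels(30, 30, 15)
        # 8-connected spur attached to the circle's topmost pixel
        top = min(circle, key=lambda p: (p[0], p[1]))
        bridge = (top[0] - 1, top[1] + 1)
        spur = {bridge, (bridge[0] - 1, bridge[1]), (bridge[0] - 2, bridge[1])}
        emap = edge_map_from_slices([circle | spur], (64, 64))
        script = EditScript(seeds={0: [min(circle)]}, remove={0: [bridge]})
        kept = initialize_slice(emap, 0, script)
        assert kept == circle

    def test_no_seeds_is_an_error(self):
        emap = edge_map_from_slices([circle_pixels(10, 10, 5)], (32, 32))
        with pytest.raises(ValueError):
            initialize_slice(emap, 0, EditScript())

    def test_seed_off_edge_is_an_error(self):
        emap = edge_map_from_slices([circle_pixels(10, 10, 5)], (32, 32))
        with pytest.raises(ValueError, match="(0, 0)"):
            initialize_slice(emap, 0, EditScript(seeds={0: [(0, 0)]}))


def brute_force_nearest(source, target, radius):
    out = set()
    for p in sorted(source):
        best = None
        for t in sorted(target):
            d = (t[0] - p[0]) ** 2 + (t[1] - p[1]) ** 2
            if d <= radius * radius and (best is None or (d, t) < best):
                best = (d, t)
        if best:
            out.add(best[1])
    return out


class TestPropagate:
    def test_identical_slices_copy_boundary(self):
        circle = circle_pixels(30, 30, 15)
        emap = edge_map_from_slices([circle, circle], (64, 64))
        bset = BoundarySet(boundary={0: set(circle)}, initialized_slices={0})
        propagate(emap, bset, radius_px=3.0)
        assert bset.boundary[1] == circle

    def test_shifted_circle_matches_exhaustive_oracle(self):
        circle = circle_pixels(30, 30, 20)
        shifted = {(r + 1, c) for r, c in circle}
        emap = edge_map_from_slices([circle, shifted], (64, 64))
        bset = BoundarySet(boundary={0: set(circle)}, initialized_slices={0})
        propagate(emap, bset, radius_px=3.0)
        oracle = brute_force_nearest(circle, shifted, 3.0)
        assert bset.boundary[1] == oracle
        assert bset.boundary[1] <= shifted
        assert len(bset.boundary[1]) >= 0.8 * len(shifted)

    def test_empty_target_warns_and_continues(self, caplog):
        circle = circle_pixels(30, 30, 15)
        empty = set()
        emap = edge_map_from_slices([circle, empty, circle], (64, 64))
        bset = BoundarySet(boundary={0: set(circle)}, initialized_slices={0})
        with caplog.at_level("WARNING"):
            propagate(emap, bset, radius_px=3.0)
        assert bset.boundary[1] == set()
        assert "no edge pixels" in caplog.text
        # slice 2 recovered from the last non-empty source (slice 0)
        assert bset.boundary[2] == circle

    def test_idempotent(self):
        circle = circle_pixels(30, 30, 15)
        shifted = {(r, c + 1) for r, c in circle}
        emap = edge_map_from_slices([circle, shifted], (64, 64))
        bset = BoundarySet(boundary={0: set(circle)}, initialized_slices={0})
        propagate(emap, bset, radius_px=3.0)
        snapshot = {k: set(v) for k, v in bset.boundary.items()}
        propagate(emap, bset, radius_px=3.0)
        assert {k: set(v) for k, v in bset.boundary.items()} == snapshot

    def test_boundary_subset_of_edges(self, noiseless_t1_phantom):
        vol, truth = noiseless_t1_phantom
        region = bone_crop_region(truth, vol.shape, 14)
        vol_c, truth_c = crop(vol, region), crop_truth(truth, region)
        emap = detect_edges(vol_c, 0.05)
        script = auto_seed_from_mask(emap, truth_c, every_n=5, dense_radius_px=2.0)
        bset = run_segmentation(emap, script, radius_px=3.0)
        removed = {k: {tuple(p) for p in script.remove.get(k, [])} for k in bset.boundary}
        for k, pixels in bset.boundary.items():
            allowed = emap.slice_pixels(k) - removed[k]
            assert pixels <= allowed


@pytest.fixture(scope="module")
def seeded_setup(noiseless_t1_phantom):
    vol, truth = noiseless_t1_phantom
    region = bone_crop_region(truth, vol.shape, 14)
    vol_c, truth_c = crop(vol, region), crop_truth(truth, region)
    return detect_edges(vol_c, 0.05), truth_c


class TestAutoSeed:
    def test_seed_count_every_five(self, seeded_setup):
        emap, truth = seeded_setup
        script = auto_seed_from_mask(emap, truth, every_n=5)
        n_bone = int(truth.bone_mask.any(axis=(1, 2)).sum())
        assert len(script.seeded_slices()) == int(np.ceil(n_bone / 5))

    def test_every_slice_when_n_is_one(self, seeded_setup):
        emap, truth = seeded_setup
        script = auto_seed_from_mask(emap, truth, every_n=1)
        n_bone = int(truth.bone_mask.any(axis=(1, 2)).sum())
        assert len(script.seeded_slices()) == n_bone

    def test_script_satisfies_initialize_preconditions(self, seeded_setup):
        emap, truth = seeded_setup
        script = auto_seed_from_mask(emap, truth, every_n=5, dense_radius_px=2.0)
        for k in script.seeded_slices():
            kept = initialize_slice(emap, k, script)
            assert kept

    def test_segmentation_tracks_truth_boundary(self, seeded_setup):
        """Seeding ~1 in 5 slices (denser at the poles, as an operator
        would) keeps the boundary within 2 px of truth — average symmetric
        surface distance — on >= 95% of slices."""
        emap, truth = seeded_setup
        script = auto_seed_from_mask(emap, truth, every_n=5, dense_radius_px=2.0)
        bset = run_segmentation(emap, script, radius_px=3.0)
        ok = 0
        slices = [k for k in range(truth.bone_mask.shape[0]) if truth.bone_mask[k].any()]
        for k in slices:
            ring = truth.bone_mask[k] & ~ndimage.binary_erosion(truth.bone_mask[k])
            pix = bset.boundary.get(k, set())
            if not pix:
                continue
            arr = np.array(sorted(pix))
            seg = np.zeros_like(ring)
            seg[arr[:, 0], arr[:, 1]] = True
            d_seg = ndimage.distance_transform_edt(~seg)
            d_ring = ndimage.distance_transform_edt(~ring)
            assd = 0.5 * (d_seg[ring].mean() + d_ring[seg].mean())
            if assd <= 2.0:
                ok += 1
        assert ok / len(slices) >= 0.95


def test_edit_script_json_round_trip(tmp_path):
    script = EditScript(seeds={12: [(3, 4), (5, 6)]}, remove={12: [(1, 1)], 7: [(2, 9)]})
    path = tmp_path / "edits.json"
    script.save(path)
    back = EditScript.load(path)
    assert back.seeds == script.seeds
    assert back.remove == script.remove
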