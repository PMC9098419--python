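import dataclasses

import numpy as np
import pytest

from boneseg import (
    Modality,
    compute_contrast,
    dice,
    generate,
    perimeter_reduce,
    surface_distance,
    weighted_dice,
)
from boneseg.model_building import SurfaceMesh, build_mesh


class TestContrast:
    @pytest.mark.parametrize("bone, cart, expected", [
        (5.0, 100.0, 0.95),
        (100.0, 100.0, 0.0),
        (28.0, 100.0, 0.72),
    ])
    def test_values(self, bone, cart, expected):
        assert compute_contrast(bone, cart).contrast == expected

    def test_zero_cartilage_rejected(self):
        with pytest.raises(ValueError):
            compute_contrast(10.0, 0.0)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:6] = True
        b.flat[3:9] = True
        assert dice(a, b) == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_one(self):
        assert dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestWeightedDice:
    def test_identical_segmentations(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        rep = weighted_dice({0: m, 1: m}, {0: m, 1: m})
        assert rep.weighted_mean == 1.0

    def test_weighted_arithmetic(self):
        # slice 0: dsc 1 with |X|+|Y| = 300; slice 1: dsc 0.5, weight 100
        a0 = np.zeros((20, 20), bool); a0.flat[:150] = True
        a1 = np.zeros((20, 20), bool); a1.flat[:50] = True
        b1 = np.zeros((20, 20), bool); b1.flat[25:75] = True
        rep = weighted_dice({0: a0, 1: a1}, {0: a0, 1: b1})
        assert rep.weighted_mean == pytest.approx(0.875)
        assert rep.weights == [300, 100]

    def test_equal_weights_match_pooled(self):
        a = np.zeros((10, 10), bool); a.flat[:20] = True
        b = np.zeros((10, 10), bool); b.flat[10:30] = True
        rep = weighted_dice({0: a, 1: a}, {0: b, 1: b})
        pooled = dice(np.stack([a, a]), np.stack([b, b]))
        assert rep.weighted_mean == pytest.approx(pooled)

    def test_no_segmented_pixels_rejected(self):
        empty = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            weighted_dice({0: empty}, {0: empty})


@pytest.fixture(scope="module")
def capped_sphere(sphere_boundary):
    """Sphere mesh with the +x cap flagged as the articular region."""
    bset, vol, R = sphere_boundary
    mesh = build_mesh(bset, vol, smoothing_iters=0)
    flags = mesh.vertices[:, 0] > 0.5 * R
    return SurfaceMesh(mesh.vertices, mesh.faces, flags), R


class TestPerimeterReduce:
    def test_zero_fraction_is_identity(self, capped_sphere):
        mesh, _ = capped_sphere
        out = perimeter_reduce(mesh, 0.0)
        assert np.array_equal(out, mesh.cartilage_face_flags)

    def test_circle_projection_shrinks_exactly(self, capped_sphere):
        """The +x cap projects to a disk; a 25% perimeter reduction keeps
        exactly the vertices whose projected radius is within 75% of it."""
        mesh, R = capped_sphere
        out = perimeter_reduce(mesh, 0.25)
        proj_r = np.linalg.norm(mesh.vertices[:, 1:3], axis=1)
        rim = proj_r[mesh.cartilage_face_flags].max()
        kept_r = proj_r[out]
        assert kept_r.max() <= 0.75 * rim + 1e-6
        inner = mesh.cartilage_face_flags & (proj_r <= 0.74 * rim)
        assert np.all(out[inner])

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.5])
    def test_retained_is_subset(self, capped_sphere, fraction):
        mesh, _ = capped_sphere
        out = perimeter_reduce(mesh, fraction)
        assert not np.any(out & ~mesh.cartilage_face_flags)
        assert out.sum() < mesh.cartilage_face_flags.sum()

    def test_empty_region_rejected(self, capped_sphere):
        mesh, _ = capped_sphere
        bare = SurfaceMesh(mesh.vertices, mesh.faces, np.zeros(len(mesh.vertices), bool))
        with pytest.raises(ValueError):
            perimeter_reduce(bare, 0.25)


class TestSurfaceDistance:
    def test_identity_is_exactly_zero(self, flat_slab_mesh):
        rep = surface_distance(flat_slab_mesh, flat_slab_mesh)
        assert np.all(rep.distances_mm == 0.0)
        assert rep.mean_mm == 0.0 and rep.sd_mm == 0.0

    def test_x_translation_recovered(self, flat_slab_mesh):
        moved = SurfaceMesh(flat_slab_mesh.vertices + [-0.5, 0.0, 0.0],
                            flat_slab_mesh.faces)
        rep = surface_distance(flat_slab_mesh, moved)
        assert rep.mean_mm == pytest.approx(0.5, abs=1e-3)
        assert rep.sd_mm < 1e-3

    def test_antisymmetric_between_models(self, flat_slab_mesh):
        moved = SurfaceMesh(flat_slab_mesh.vertices + [-0.3, 0.0, 0.0],
                            flat_slab_mesh.faces,
                            flat_slab_mesh.cartilage_face_flags)
        ab = surface_distance(flat_slab_mesh, moved)
        ba = surface_distance(moved, flat_slab_mesh)
        assert ab.mean_mm == pytest.approx(-ba.mean_mm, abs=0.02)

    def test_mean_recomputable_from_distances(self, flat_slab_mesh):
        moved = SurfaceMesh(flat_slab_mesh.vertices + [-0.2, 0.1, 0.0],
                            flat_slab_mesh.faces)
        rep = surface_distance(flat_slab_mesh, moved)
        assert rep.mean_mm == pytest.approx(float(rep.distances_mm.mean()))
        assert rep.matched_count + rep.unmatched_count == int(
            perimeter_reduce(flat_slab_mesh, 0.25).sum())

    def test_unmatched_grows_as_radius_shrinks(self, flat_slab_mesh):
        moved = SurfaceMesh(flat_slab_mesh.vertices + [0.3, 0.0, 0.0],
                            flat_slab_mesh.faces)
        unmatched = []
        for r in (0.35, 0.32, 0.305):
            rep = surface_distance(flat_slab_mesh, moved, radius_mm=r)
            unmatched.append(rep.unmatched_count)
        assert unmatched == sorted(unmatched)

    def test_independent_renderings_agree(self, noiseless_t1_phantom):
        """Two segmentations of the same noiseless phantom, initialized on
        different slices, produce meshes whose articular surfaces agree to
        a few hundredths of a millimetre."""
        from boneseg.experiments import ExperimentConfig, segment_phantom

        vol, truth = noiseless_t1_phantom
        cfg = ExperimentConfig(seeds=(1, 2))
        a = segment_phantom(vol, truth, cfg, 0)
        b = segment_phantom(vol, truth, cfg, 1)
        rep = surface_distance(a.mesh, b.mesh)
        assert abs(rep.mean_mm) < 0.05
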