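import numpy as np
import pytest

from conftest import make_mask
from fibrometry import (
    Calibration,
    PolygonAnnotation,
    Skeleton,
    distance_transform,
    longest_skeleton_path,
    measure_collection,
    measure_instance,
    skeleton_length_px,
    thin_mask,
    touches_border,
    width_px,
    zhang_suen_thin,
)
from fibrometry.synthetic import render_instance
from oracles import (
    all_pairs_longest_path_length,
    brute_force_distance_transform,
    zhang_suen_reference,
)


def ring(size=15, thickness=1):
    g = np.zeros((size, size), dtype=bool)
    g[2, 2:-2] = g[-3, 2:-2] = True
    g[2:-2, 2] = g[2:-2, -3] = True
    return g


THINNING_FIXTURES = {
    "single_pixel": np.ones((1, 1), dtype=bool),
    "bar_3x9": np.ones((3, 9), dtype=bool),
    "ring_1px": ring(),
    "blob_L": np.pad(
        np.array([[1] * 12] * 4 + [[1] * 4 + [0] * 8] * 8, dtype=bool), 2
    ),
    "diagonal_band": np.tri(20, 20, 2, dtype=bool) & ~np.tri(20, 20, -3, dtype=bool),
}


class TestThinning:
    @pytest.mark.parametrize("name", sorted(THINNING_FIXTURES))
    def test_matches_reference_zhang_suen(self, name):
        grid = THINNING_FIXTURES[name]
        ours = zhang_suen_thin(grid)
        ref = zhang_suen_reference(grid)
        np.testing.assert_array_equal(ours, ref)

    def test_single_pixel_is_fixpoint(self):
        out = zhang_suen_thin(np.ones((1, 1), dtype=bool))
        assert out.sum() == 1

    def test_ring_preserved(self):
        g = ring()
        np.testing.assert_array_equal(zhang_suen_thin(g), g)

    def test_output_subset_of_input(self, small_scene):
        for inst in small_scene.instances[:3]:
            sk = thin_mask(inst.full_mask)
            assert not (sk.grid & ~inst.full_mask.grid).any()

    def test_connectivity_preserved(self, small_scene):
        from scipy import ndimage

        s8 = np.ones((3, 3), dtype=int)
        for inst in small_scene.instances[:3]:
            _, n_in = ndimage.label(inst.full_mask.grid, structure=s8)
            _, n_out = ndimage.label(thin_mask(inst.full_mask).grid, structure=s8)
            assert n_in == n_out

    def test_synthetic_instances_match_reference(self, small_scene):
        inst = small_scene.instances[0]
        np.testing.assert_array_equal(
            zhang_suen_thin(inst.full_mask.grid),
            zhang_suen_reference(inst.full_mask.grid),
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(Exception, match="foreground"):
            make_mask(np.zeros((3, 3), dtype=bool))


class TestLongestPath:
    def test_straight_row_in_order(self):
        sk = Skeleton(grid=np.ones((1, 10), dtype=bool))
        path = longest_skeleton_path(sk)
        assert len(path) == 10
        assert path[0] == (0, 0) and path[-1] == (0, 9)

    def test_t_shape_takes_crossbar(self):
        g = np.zeros((5, 9), dtype=bool)
        g[0, :] = True          # crossbar, 9 px
        g[0:5, 4] = True        # stem, 5 px incl. the shared center
        path = longest_skeleton_path(Skeleton(grid=g))
        assert len(path) == all_pairs_longest_path_length(g) == 9

    def test_single_pixel(self):
        path = longest_skeleton_path(Skeleton(grid=np.ones((1, 1), dtype=bool)))
        assert path == [(0, 0)]

    def test_path_steps_are_8_adjacent(self, small_scene):
        sk = thin_mask(small_scene.instances[0].full_mask)
        path = longest_skeleton_path(sk)
        for a, b in zip(path, path[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    @pytest.mark.parametrize("name", ["bar_3x9", "blob_L", "diagonal_band"])
    def test_double_bfs_matches_all_pairs_on_trees(self, name):
        sk_grid = zhang_suen_thin(THINNING_FIXTURES[name])
        assert len(longest_skeleton_path(Skeleton(grid=sk_grid))) == \
            all_pairs_longest_path_length(sk_grid)

    def test_exact_mode_matches_all_pairs_with_cycle(self):
        g = ring(11)
        g[6, 8:11] = True  # ring plus a tail
        assert len(longest_skeleton_path(Skeleton(grid=g), exact=True)) == \
            all_pairs_longest_path_length(g)


class TestSkeletonLength:
    def test_straight_row_pixel_count(self):
        sk = Skeleton(grid=np.ones((1, 100), dtype=bool))
        assert skeleton_length_px(sk, "pixel_count") == 100.0

    def test_diagonal_weighted_vs_count(self):
        sk = Skeleton(grid=np.eye(10, dtype=bool))
        assert skeleton_length_px(sk, "pixel_count") == 10.0
        assert skeleton_length_px(sk, "weighted_path") == pytest.approx(9 * np.sqrt(2))

    def test_l_path_matches_bfs_oracle(self):
        # two 5-px axial arms sharing a corner: the 8-connected breadth-first
        # path steps diagonally past the corner pixel (8 px, 6 + sqrt(2))
        g = np.zeros((5, 5), dtype=bool)
        g[4, :] = True
        g[:, 0] = True
        sk = Skeleton(grid=g)
        assert skeleton_length_px(sk, "pixel_count") == \
            all_pairs_longest_path_length(g) == 8.0
        assert skeleton_length_px(sk, "weighted_path") == \
            pytest.approx(6.0 + np.sqrt(2))

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            skeleton_length_px(Skeleton(grid=np.ones((1, 3), dtype=bool)), "arc")


class TestDistanceTransform:
    def test_single_pixel(self):
        dt = distance_transform(make_mask([[1]]))
        assert dt[0, 0] == 1.0

    def test_7x7_square_center(self):
        dt = distance_transform(make_mask(np.ones((7, 7), dtype=bool)))
        assert dt.max() == 4.0
        assert dt[3, 3] == 4.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((24, 32)) < 0.6
        grid[12, 16] = True
        np.testing.assert_allclose(
            distance_transform(make_mask(grid)),
            brute_force_distance_transform(grid),
        )

    def test_synthetic_mask_matches_brute_force(self):
        mask, _ = render_instance(np.array([[8.0, 20.0], [40.0, 28.0]]), 7.0)
        sub = mask.grid[:50, :60]
        np.testing.assert_allclose(
            distance_transform(make_mask(sub)),
            brute_force_distance_transform(sub),
        )


class TestWidth:
    def test_seven_row_band(self):
        band = make_mask(np.ones((7, 40), dtype=bool))
        assert width_px(band) == 8.0
        assert width_px(band, bias_correction=True) == 7.0

    def test_single_pixel_line(self):
        assert width_px(make_mask(np.ones((1, 30), dtype=bool))) == 2.0

    def test_disk_radius_10(self):
        yy, xx = np.mgrid[:23, :23]
        disk = (yy - 11.0) ** 2 + (xx - 11.0) ** 2 <= 10.0 ** 2
        assert 20.0 <= width_px(make_mask(disk)) <= 22.0

    def test_dilation_monotonicity(self, small_scene):
        from scipy import ndimage

        for inst in small_scene.instances[:3]:
            grown = ndimage.binary_dilation(
                np.pad(inst.full_mask.grid, 1), np.ones((3, 3), dtype=bool)
            )
            assert width_px(make_mask(grown)) >= width_px(inst.full_mask)


class TestBorder:
    def test_polygon_vertex_on_edge(self):
        poly = PolygonAnnotation("fiber", [(0.0, 5.0), (4.0, 5.0), (2.0, 9.0)])
        assert touches_border(poly, 100, 100)

    def test_interior_mask_margin0(self):
        assert not touches_border(make_mask([[1]], offset=(5, 5)), 100, 100)

    def test_interior_mask_margin2(self):
        mask = make_mask([[1]], offset=(2, 50))
        assert not touches_border(mask, 100, 100, margin=0)
        assert touches_border(mask, 100, 100, margin=2)


class TestMeasurement:
    def test_micron_calibration_exact(self, small_scene):
        cal = Calibration(0.65)
        rec = measure_instance(
            small_scene.instances[0].full_mask, cal, 640, 640
        )
        assert rec.length_um == pytest.approx(rec.length_px * 0.65, rel=1e-12)
        assert rec.area_um2 == pytest.approx(rec.area_px2 * 0.65 ** 2, rel=1e-12)

    def test_straight_fiber_length_and_width(self):
        mask, _ = render_instance(
            np.array([[20.0, 40.0], [220.0, 40.0]]), 9.0, instance_id="f"
        )
        rec = measure_instance(mask, Calibration(), 300, 300)
        assert 180.0 <= rec.length_px <= 205.0
        assert 8.0 <= rec.width_px <= 11.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_flip_invariance(self, small_scene, k):
        inst = small_scene.instances[1].full_mask
        base = measure_instance(make_mask(inst.grid), Calibration(), 2000, 2000,
                                length_mode="weighted_path")
        rot = measure_instance(make_mask(np.rot90(inst.grid, k)), Calibration(),
                               2000, 2000, length_mode="weighted_path")
        flip = measure_instance(make_mask(inst.grid[:, ::-1]), Calibration(),
                                2000, 2000, length_mode="weighted_path")
        for other in (rot, flip):
            assert other.length_px == pytest.approx(base.length_px)
            assert other.width_px == pytest.approx(base.width_px)
            assert other.area_px2 == base.area_px2

    def test_stadium_bounds(self):
        # constant-width stadium, L >= 5w: width within +-2, length within
        # [L - 1.5w, L + 2] for the pixel-count mode
        L, w = 150.0, 11.0
        mask, _ = render_instance(np.array([[10.0, 30.0], [160.0, 30.0]]), w)
        rec = measure_instance(mask, Calibration(), 200, 200)
        assert abs(rec.width_px - w) <= 2.0
        assert L - 1.5 * w <= rec.length_px <= L + 2.0

    def test_border_filter_semantics(self):
        interior = [make_mask([[1]], offset=(50, 50 + i)) for i in range(3)]
        border = [make_mask([[1]], offset=(0, i)) for i in range(2)]
        records = measure_collection(
            interior + border, Calibration(), 100, 100, exclude_border=True
        )
        assert len(records) == 5
        assert sum(not r.excluded for r in records) == 3
        records_all = measure_collection(
            interior + border, Calibration(), 100, 100, exclude_border=False
        )
        assert sum(not r.excluded for r in records_all) == 5

    def test_overlapping_instances_measured_independently(self):
        a = make_mask(np.ones((5, 20), dtype=bool), offset=(10, 10))
        b = make_mask(np.ones((5, 20), dtype=bool), offset=(12, 10))
        recs = measure_collection([a, b], Calibration(), 100, 100)
        assert recs[0].area_px2 == recs[1].area_px2 == 100.0
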