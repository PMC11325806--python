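import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrometry.annotation_io import AnnotationError
from fibrometry import (
    ImageAnnotationSet,
    PolygonAnnotation,
    augment,
    polygon_area_px2,
    rasterize_polygon,
    read_vgg_json,
    read_yolo_seg_labels,
    split_manifest,
    tile_image,
    write_vgg_json,
    write_yolo_seg_labels,
)
from oracles import brute_force_rasterize_count

SQUARE = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]


def via_project(regions_by_image):
    """Build a VIA project-dialect JSON string."""
    meta = {}
    for image_id, regions in regions_by_image.items():
        meta[image_id] = {
            "filename": image_id,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [p[0] for p in pts],
                        "all_points_y": [p[1] for p in pts],
                    },
                    "region_attributes": {"label": label},
                }
                for label, pts in regions
            ],
        }
    return json.dumps({"_via_img_metadata": meta})


class TestVggJson:
    def test_single_fiber_polygon(self, tmp_path):
        path = tmp_path / "via.json"
        path.write_text(via_project({"img1.png": [("fiber", SQUARE)]}))
        sets = read_vgg_json(path)
        assert len(sets) == 1
        assert len(sets[0].annotations) == 1
        ann = sets[0].annotations[0]
        assert ann.class_label == "fiber"
        assert ann.n_vertices == 4

    def test_two_point_region_dropped(self, tmp_path, caplog):
        path = tmp_path / "via.json"
        path.write_text(via_project({"img1.png": [("fiber", SQUARE[:2])]}))
        with caplog.at_level("WARNING", logger="fibrometry"):
            sets = read_vgg_json(path)
        assert sets[0].annotations == []
        assert any("fewer than 3 points" in r.message for r in caplog.records)

    def test_two_images_one_empty(self, tmp_path):
        path = tmp_path / "via.json"
        path.write_text(via_project({
            "a.png": [("vessel", SQUARE)],
            "b.png": [],
        }))
        sets = read_vgg_json(path)
        assert len(sets) == 2
        assert [len(s.annotations) for s in sets] == [1, 0]

    def test_unknown_label_preserved_with_warning(self, tmp_path, caplog):
        path = tmp_path / "via.json"
        path.write_text(via_project({"a.png": [("ray_cell", SQUARE)]}))
        with caplog.at_level("WARNING", logger="fibrometry"):
            sets = read_vgg_json(path)
        assert sets[0].annotations[0].class_label == "ray_cell"
        assert any("unknown class" in r.message for r in caplog.records)

    def test_malformed_json_names_file(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(AnnotationError, match="broken.json"):
            read_vgg_json(path)

    def test_missing_shape_attributes_not_fatal(self, tmp_path, caplog):
        data = {"a.png": {"filename": "a.png", "regions": [
            {"region_attributes": {"label": "fiber"}},
            {"shape_attributes": {"name": "polygon",
                                  "all_points_x": [0, 10, 10, 0],
                                  "all_points_y": [0, 0, 10, 10]},
             "region_attributes": {"label": "fiber"}},
        ]}}
        path = tmp_path / "via.json"
        path.write_text(json.dumps(data))
        with caplog.at_level("ERROR", logger="fibrometry"):
            sets = read_vgg_json(path)
        assert len(sets[0].annotations) == 1

    def test_round_trip_preserves_vertices(self, tmp_path):
        aset = ImageAnnotationSet(
            image_id="x.png", width_px=200, height_px=100,
            annotations=[PolygonAnnotation("vessel", SQUARE)],
        )
        path = tmp_path / "rt.json"
        write_vgg_json([aset], path)
        back = read_vgg_json(path)[0]
        assert back.width_px == 200 and back.height_px == 100
        np.testing.assert_allclose(
            back.annotations[0].vertices, aset.annotations[0].vertices
        )


class TestYoloSeg:
    def test_square_line(self):
        aset = ImageAnnotationSet(
            "i", 100, 100, [PolygonAnnotation("fiber", SQUARE)]
        )
        lines = write_yolo_seg_labels(aset, ["fiber", "vessel"])
        assert lines == [
            "0 0.000000 0.000000 0.100000 0.000000 "
            "0.100000 0.100000 0.000000 0.100000"
        ]

    def test_vessel_class_index(self):
        aset = ImageAnnotationSet(
            "i", 100, 100, [PolygonAnnotation("vessel", SQUARE)]
        )
        assert write_yolo_seg_labels(aset, ["fiber", "vessel"])[0].startswith("1 ")

    def test_unlisted_label_rejected(self):
        aset = ImageAnnotationSet(
            "i", 100, 100, [PolygonAnnotation("ray", SQUARE)]
        )
        with pytest.raises(AnnotationError, match="ray"):
            write_yolo_seg_labels(aset, ["fiber", "vessel"])

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1023).map(lambda v: round(v, 3)),
                st.floats(0, 767).map(lambda v: round(v, 3)),
            ),
            min_size=3, max_size=12,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_round_trip_within_tolerance(self, pts):
        aset = ImageAnnotationSet(
            "i", 1024, 768, [PolygonAnnotation("fiber", pts)]
        )
        lines = write_yolo_seg_labels(aset, ["fiber"])
        back = read_yolo_seg_labels(lines, ["fiber"], 1024, 768)
        np.testing.assert_allclose(
            back.annotations[0].vertices, aset.annotations[0].vertices,
            atol=1e-5 * 1024,
        )


class TestRasterize:
    def test_square_boundary_inclusive(self):
        mask = rasterize_polygon(PolygonAnnotation("fiber", SQUARE), 100, 100)
        assert mask.area_px == 121
        assert mask.grid.shape == (11, 11)

    @pytest.mark.parametrize("verts", [
        [(0, 0), (4, 0), (0, 3)],
        [(1.5, 0.5), (8.2, 2.0), (6.0, 9.0), (0.5, 6.5)],
        [(0, 0), (10, 0), (0, 10), (10, 10)],  # self-intersecting bowtie
    ])
    def test_count_matches_brute_force(self, verts):
        mask = rasterize_polygon(PolygonAnnotation("fiber", verts), 16, 16)
        assert mask.area_px == brute_force_rasterize_count(np.array(verts, float), 16, 16)

    def test_collinear_polygon_rejected(self):
        with pytest.raises(AnnotationError, match="degenerate"):
            rasterize_polygon(
                PolygonAnnotation("fiber", [(0, 0), (5, 5), (10, 10)]), 20, 20
            )

    @given(
        st.lists(
            st.tuples(st.integers(0, 15), st.integers(0, 15)),
            min_size=3, max_size=8,
        ).filter(
            lambda pts: polygon_area_px2(np.array(pts, float)) > 0
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_random_polygons_match_oracle(self, pts):
        mask = rasterize_polygon(PolygonAnnotation("fiber", pts), 16, 16)
        assert mask.area_px == brute_force_rasterize_count(np.array(pts, float), 16, 16)


class TestPolygonArea:
    @pytest.mark.parametrize("verts,expected", [
        (SQUARE, 100.0),
        ([(0, 0), (4, 0), (0, 3)], 6.0),
        (SQUARE[::-1], 100.0),
    ])
    def test_shoelace(self, verts, expected):
        assert polygon_area_px2(PolygonAnnotation("fiber", verts)) == expected


class TestTiling:
    def test_exact_quarters(self):
        wins = tile_image(2048, 2048, 1024, 0.0)
        assert wins == [
            (0, 0, 1024, 1024), (0, 1024, 1024, 1024),
            (1024, 0, 1024, 1024), (1024, 1024, 1024, 1024),
        ]

    def test_small_image_single_window(self):
        assert tile_image(1000, 1000, 1024) == [(0, 0, 1000, 1000)]

    @pytest.mark.parametrize("w,h,tile,overlap", [
        (3000, 2000, 1024, 0.1), (1500, 900, 512, 0.25), (640, 640, 256, 0.0),
    ])
    def test_full_coverage_and_containment(self, w, h, tile, overlap):
        wins = tile_image(w, h, tile, overlap)
        painted = np.zeros((h, w), dtype=bool)
        for r0, c0, rows, cols in wins:
            assert r0 + rows <= h and c0 + cols <= w
            painted[r0:r0 + rows, c0:c0 + cols] = True
        assert painted.all()

    def test_bad_overlap_rejected(self):
        with pytest.raises(ValueError):
            tile_image(1000, 1000, 512, 1.0)


class TestAugment:
    @pytest.fixture
    def aset(self):
        return ImageAnnotationSet(
            "i", 200, 100,
            [PolygonAnnotation("fiber", [(10.0, 20.0), (50.0, 20.0), (30.0, 80.0)])],
        )

    def test_fliph_closed_form(self, aset):
        out = augment(aset, "fliph")
        np.testing.assert_allclose(
            out.annotations[0].vertices[:, 0],
            200 - aset.annotations[0].vertices[:, 0],
        )
        np.testing.assert_allclose(
            out.annotations[0].vertices[:, 1], aset.annotations[0].vertices[:, 1]
        )

    def test_rot90_twice_is_rot180(self, aset):
        twice = augment(augment(aset, "rot90"), "rot90")
        once = augment(aset, "rot180")
        np.testing.assert_allclose(
            twice.annotations[0].vertices, once.annotations[0].vertices
        )

    def test_scale_area_quadratic(self, aset):
        out = augment(aset, "scale(0.5)")
        assert polygon_area_px2(out.annotations[0]) == pytest.approx(
            0.25 * polygon_area_px2(aset.annotations[0])
        )

    @pytest.mark.parametrize("op,inverse", [
        ("fliph", "fliph"), ("flipv", "flipv"),
        ("rot90", "rot270"), ("rot180", "rot180"),
    ])
    def test_invertible(self, aset, op, inverse):
        back = augment(augment(aset, op), inverse)
        np.testing.assert_allclose(
            back.annotations[0].vertices, aset.annotations[0].vertices, atol=1e-9
        )

    def test_scale_reciprocal_inverts(self, aset):
        back = augment(augment(aset, "scale", factor=2.0), "scale", factor=0.5)
        np.testing.assert_allclose(
            back.annotations[0].vertices, aset.annotations[0].vertices, atol=1e-9
        )

    def test_unknown_op_rejected(self, aset):
        with pytest.raises(ValueError, match="unknown"):
            augment(aset, "shear")


class TestSplitManifest:
    def test_85_15(self):
        ids = [f"img{i}" for i in range(100)]
        train, val = split_manifest(ids, 0.85, seed=1)
        assert len(train) == 85 and len(val) == 15
        assert set(train) | set(val) == set(ids)
        assert not set(train) & set(val)

    def test_deterministic(self):
        ids = [f"img{i}" for i in range(30)]
        assert split_manifest(ids, 0.85, seed=7) == split_manifest(ids, 0.85, seed=7)

    def test_rounding(self):
        ids = [f"img{i}" for i in range(20)]
        train, val = split_manifest(ids, 0.85, seed=0)
        assert (len(train), len(val)) == (17, 3)

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            split_manifest(["only"], 0.85, seed=0)
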