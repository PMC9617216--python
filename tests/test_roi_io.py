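"""TPS parsing, polygon joins, rasterization, mask tracing, label JSON."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from coilmask import roi_io
from conftest import random_blob_mask


def brute_force_rasterize(vertices, image_size):
    """Independent even-odd pixel-center oracle (scalar crossing count)."""
    h, w = image_size
    out = np.zeros((h, w), dtype=bool)
    n = len(vertices)
    for r in range(h):
        for c in range(w):
            px, py = c + 0.5, r + 0.5
            crossings = 0
            for i in range(n):
                x1, y1 = vertices[i]
                x2, y2 = vertices[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        crossings += 1
            out[r, c] = crossings % 2 == 1
    return out


class TestReadTps:
    def test_single_record_with_image(self):
        chains = roi_io.read_tps("LM=2\n1.0 2.0\n3.0 4.0\nIMAGE=a.jpg")
        assert len(chains) == 1
        assert chains[0].points == [(1.0, 2.0), (3.0, 4.0)]
        assert chains[0].image == "a.jpg"

    def test_empty_record_tolerated_with_warning(self):
        with pytest.warns(UserWarning, match="LM=0"):
            chains = roi_io.read_tps("LM=0\nIMAGE=b.jpg")
        assert len(chains) == 1
        assert chains[0].points == []

    def test_two_records_in_file_order(self):
        text = "LM=1\n1 1\nIMAGE=x.jpg\nLM=2\n2 2\n3 3\nIMAGE=y.jpg\n"
        chains = roi_io.read_tps(text)
        assert [len(c.points) for c in chains] == [1, 2]
        assert [c.image for c in chains] == ["x.jpg", "y.jpg"]

    def test_short_record_is_parse_error_naming_record(self):
        with pytest.raises(roi_io.TPSParseError, match="record 1"):
            roi_io.read_tps("LM=3\n1 1\n2 2\nIMAGE=a.jpg")

    def test_bottom_left_origin_flips_y(self):
        chains = roi_io.read_tps(
            "LM=1\n5 10\n", origin="bottom-left", image_height=100
        )
        assert chains[0].points == [(5.0, 90.0)]

    def test_roundtrip_write_read_six_sig_digits(self, rng):
        pts = [(float(x), float(y)) for x, y in rng.uniform(0, 999, size=(12, 2))]
        chains = [roi_io.LandmarkChain(points=pts, image="z.jpg", record_id="7")]
        back = roi_io.read_tps(roi_io.write_tps(chains))
        assert back[0].image == "z.jpg"
        for (x0, y0), (x1, y1) in zip(pts, back[0].points):
            assert x1 == pytest.approx(x0, rel=1e-5)
            assert y1 == pytest.approx(y0, rel=1e-5)


class TestChainsToPolygon:
    def test_single_chain_identity(self):
        square = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        poly = roi_io.chains_to_polygon([square])
        assert poly.vertices == tuple(square)

    def test_two_chains_second_reversed(self):
        poly = roi_io.chains_to_polygon([[(0, 0), (10, 0)], [(0, 2), (10, 2)]])
        assert poly.vertices == ((0, 0), (10, 0), (10, 2), (0, 2))

    def test_unreversed_join_warns_bowtie(self):
        with pytest.warns(UserWarning, match="self-intersecting"):
            roi_io.chains_to_polygon(
                [[(0, 0), (10, 0)], [(0, 2), (10, 2)]], reverse_second=False
            )

    def test_three_chains_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous"):
            roi_io.chains_to_polygon([[(0, 0)], [(1, 1)], [(2, 2)]])


class TestRasterize:
    def test_square_example_nine_pixels(self):
        poly = roi_io.PolygonROI(vertices=((0, 0), (3, 0), (3, 3), (0, 3)))
        mask = roi_io.rasterize(poly, (5, 5))
        expected = np.zeros((5, 5), dtype=bool)
        expected[:3, :3] = True
        assert np.array_equal(mask, expected)

    def test_full_cover_polygon_all_ones(self):
        poly = roi_io.PolygonROI(vertices=((0, 0), (8, 0), (8, 6), (0, 6)))
        assert roi_io.rasterize(poly, (6, 8)).all()

    def test_zero_area_polygon_empty_with_warning(self):
        poly = roi_io.PolygonROI(vertices=((1, 1), (3, 3), (5, 5)))
        with pytest.warns(UserWarning, match="zero-area"):
            assert not roi_io.rasterize(poly, (8, 8)).any()

    def test_out_of_bounds_vertices_clamped(self):
        poly = roi_io.PolygonROI(vertices=((-5, -5), (20, -5), (20, 20), (-5, 20)))
        assert roi_io.rasterize(poly, (4, 4)).all()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        verts = [(float(x), float(y)) for x, y in r.uniform(0, 12, size=(5, 2))]
        poly = roi_io.PolygonROI(vertices=tuple(verts))
        got = roi_io.rasterize(poly, (12, 12))
        assert np.array_equal(got, brute_force_rasterize(verts, (12, 12)))

    def test_monotone_nested_squares(self):
        inner = roi_io.PolygonROI(vertices=((3, 3), (7, 3), (7, 7), (3, 7)))
        outer = roi_io.PolygonROI(vertices=((1, 1), (9, 1), (9, 9), (1, 9)))
        mi, mo = roi_io.rasterize(inner, (11, 11)), roi_io.rasterize(outer, (11, 11))
        assert not (mi & ~mo).any()


class TestMaskToPolygons:
    def test_empty_mask_empty_list(self):
        assert roi_io.mask_to_polygons(np.zeros((5, 5), dtype=bool)) == []

    def test_square_roundtrip_exact(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:14, 6:16] = True
        polys = roi_io.mask_to_polygons(mask)
        assert len(polys) == 1
        assert np.array_equal(roi_io.rasterize(polys[0], mask.shape), mask)

    def test_two_disjoint_blobs_two_polygons(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:5, 1:5] = True
        mask[10:16, 10:16] = True
        assert len(roi_io.mask_to_polygons(mask)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_roundtrip_interior_exact_on_random_blobs(self, seed):
        r = np.random.default_rng(seed)
        mask = random_blob_mask(r)
        mask = ndi.binary_fill_holes(mask)  # outer-contour representation
        recon = np.zeros_like(mask)
        for poly in roi_io.mask_to_polygons(mask):
            recon |= roi_io.rasterize(poly, mask.shape)
        disagree = recon ^ mask
        interior = ndi.binary_erosion(mask, np.ones((3, 3)))
        exterior_far = ~ndi.binary_dilation(mask, np.ones((3, 3)))
        assert not (disagree & interior).any()
        assert not (disagree & exterior_far).any()


class TestLabelJson:
    def test_roundtrip_two_classes(self, tmp_path):
        label = roi_io.LabelFile(
            image_id="img7",
            height=50,
            width=60,
            rois=[
                roi_io.PolygonROI(((1, 1), (9, 1), (9, 9)), region_class="specimen"),
                roi_io.PolygonROI(((20, 20), (30, 20), (25, 30)), region_class="gray_standard"),
            ],
        )
        p = tmp_path / "l.json"
        roi_io.write_labels(label, p)
        back = roi_io.read_labels(p)
        assert back.image_id == "img7"
        assert (back.height, back.width) == (50, 60)
        assert [r.region_class for r in back.rois] == ["specimen", "gray_standard"]
        assert back.rois[0].vertices == label.rois[0].vertices

    def test_missing_rois_key_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"schema_version": 1, "image_id": "x", "height": 5, "width": 5}))
        with pytest.raises(roi_io.LabelSchemaError, match="rois"):
            roi_io.read_labels(p)

    def test_unknown_schema_version_rejected(self, tmp_path):
        p = tmp_path / "v9.json"
        p.write_text(json.dumps({"schema_version": 9, "image_id": "x", "height": 5,
                                 "width": 5, "rois": []}))
        with pytest.raises(roi_io.LabelSchemaError, match="version"):
            roi_io.read_labels(p)

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            roi_io.PolygonROI(vertices=((0, 0), (1, 1)))
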