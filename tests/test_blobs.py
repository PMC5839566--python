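"""ROI cropping, colour segmentation, morphology, blobs, area filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from flowcount import FlowSceneSpec, MorphParams, RoiConfig, color_segment, \
    crop_roi, detect_blobs, filter_by_area, generate_flow_video, \
    morphological_clean
from flowcount.blobs import Blob, ColorSegmenter


class TestRoi:
    def test_full_frame_roi_is_identity(self):
        frame = np.arange(12, dtype=np.uint8).reshape(3, 4)
        roi = RoiConfig(0, 0, 4, 3)
        assert np.array_equal(crop_roi(frame, roi), frame)

    def test_crop_origin_maps_to_source_pixel(self):
        frame = np.zeros((480, 640), np.uint8)
        frame[10, 10] = 42
        sub = crop_roi(frame, RoiConfig(10, 10, 100, 50))
        assert sub.shape == (50, 100)
        assert sub[0, 0] == 42

    def test_blob_coordinates_reported_full_frame(self):
        mask = np.zeros((50, 100), bool)
        mask[5:15, 5:25] = True  # local (5,5), offset (10,10)
        blobs = detect_blobs(mask, offset=(10, 10))
        assert len(blobs) == 1
        assert blobs[0].bbox == (15, 15, 20, 10)
        assert blobs[0].centroid == (19.5, 24.5)

    def test_rejects_roi_outside_frame(self):
        with pytest.raises(ValueError):
            crop_roi(np.zeros((40, 40)), RoiConfig(30, 30, 20, 20))


class TestColorSegmentation:
    def test_two_region_image_gives_two_segments(self):
        frame = np.zeros((40, 40, 3), np.uint8)
        frame[:, :20] = (200, 50, 50)
        frame[:, 20:] = (50, 50, 200)
        seg = ColorSegmenter(n_clusters=3, seed=0).fit(frame)
        assert seg.n_segments(frame) == 2

    def test_uniform_image_gives_one_segment(self):
        frame = np.full((40, 40, 3), 90, np.uint8)
        seg = ColorSegmenter(seed=0).fit(frame)
        assert seg.n_segments(frame) == 1

    def test_grayscale_passthrough_with_warning(self, caplog):
        frame = np.full((10, 10), 50, np.uint8)
        with caplog.at_level("WARNING", logger="flowcount"):
            out = color_segment(frame)
        assert out is frame
        assert "grayscale" in caplog.text

    def test_increases_contrast_on_low_contrast_scene(self):
        spec = FlowSceneSpec(n_objects=1, contrast_mode="low", seed=23)
        frames, gt = generate_flow_video(spec)
        from flowcount.synthetic import object_silhouette
        f = gt.targets[0].crossing_frame
        frame = frames[f]
        sil = object_silhouette(spec, gt, f)
        band = np.zeros(sil.shape, bool)
        band[spec.channel_top + 5:spec.channel_bottom - 5] = True
        gray_before = frame.astype(float) @ [0.2125, 0.7154, 0.0721]
        seg = ColorSegmenter(n_clusters=3, seed=0).fit(frame)
        after = seg.transform(frame).astype(float)

        def contrast(img):
            return abs(img[sil].mean() - img[band & ~sil].mean())

        assert contrast(after) > contrast(gray_before)
        assert contrast(after) > 50


class TestMorphology:
    def test_empty_mask_stays_empty(self):
        mask = np.zeros((30, 30), bool)
        out = morphological_clean(mask, MorphParams())
        assert out.dtype == bool and out.sum() == 0

    def test_one_pixel_gap_is_closed(self):
        mask = np.zeros((40, 60), bool)
        mask[10:30, 10:30] = True
        mask[10:30, 31:50] = True  # 1-px gap at column 30
        assert ndi.label(mask)[1] == 2
        out = morphological_clean(mask, MorphParams(element_shape="rectangle",
                                                    element_size=5))
        assert ndi.label(out)[1] == 1

    def test_single_pixel_specks_removed(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((60, 60), bool)
        mask.flat[rng.choice(mask.size, 30, replace=False)] = True
        out = morphological_clean(mask, MorphParams(element_shape="rectangle",
                                                    element_size=3,
                                                    erode_iterations=1,
                                                    dilate_iterations=0))
        assert out.sum() == 0

    @pytest.mark.parametrize("shape,size", [("ellipse", (7, 5)),
                                            ("rectangle", 5)])
    def test_footprints_build(self, shape, size):
        fp = MorphParams(element_shape=shape, element_size=size).footprint()
        assert fp.any()

    def test_rejects_unknown_element(self):
        with pytest.raises(ValueError):
            MorphParams(element_shape="hexagon").footprint()


class TestDetectBlobs:
    def test_rectangle_geometry(self):
        mask = np.zeros((40, 60), bool)
        mask[10:20, 5:25] = True
        blobs = detect_blobs(mask)
        assert len(blobs) == 1
        b = blobs[0]
        assert b.area == 200
        assert b.bbox == (5, 10, 20, 10)
        assert b.centroid == (14.5, 14.5)
        assert len(b.contour) > 0

    def test_count_matches_connected_components_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            mask = ndi.binary_dilation(
                rng.random((50, 70)) > 0.97, iterations=2)
            assert len(detect_blobs(mask)) == \
                ndi.label(mask, structure=np.ones((3, 3)))[1]

    def test_empty_mask_gives_no_blobs(self):
        assert detect_blobs(np.zeros((20, 20), bool)) == []


def _blob(area):
    return Blob(contour=np.zeros((0, 2)), area=float(area),
                centroid=(0.0, 0.0), bbox=(0, 0, 1, 1))


class TestAreaFilter:
    def test_selects_in_range_blobs(self):
        blobs = [_blob(a) for a in (30, 150, 5000)]
        out = filter_by_area(blobs, 100, 1000)
        assert [b.area for b in out] == [150]

    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            filter_by_area([], 100, 100)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1, max_value=1e5), max_size=20),
           st.floats(min_value=1, max_value=1e4))
    def test_subset_and_idempotent(self, areas, lo):
        blobs = [_blob(a) for a in areas]
        out = filter_by_area(blobs, lo, lo + 500)
        out_ids = [id(b) for b in out]
        assert set(out_ids) <= {id(b) for b in blobs}
        assert [id(b) for b in filter_by_area(out, lo, lo + 500)] == out_ids
        kept = [id(b) for b in blobs if id(b) in out_ids]
        assert kept == out_ids  # order preserved
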