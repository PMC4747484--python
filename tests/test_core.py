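"""Pixel-level primitives: grayscale conversion, ROI masking, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import calscore as cs
from calscore.core import FormatError, GeometryError


class TestRgbToGray:
    @pytest.mark.parametrize(
        "value,expected",
        [(0, 0), (255, 250), (100, 98)],  # 100 * 250 / 255 = 98.04 -> 98
    )
    def test_achromatic_pixels_rescale_to_us_range(self, value, expected):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        frame[1, 2] = value
        gray = cs.rgb_to_gray(frame)
        assert gray[1, 2] == expected
        assert gray.dtype == np.uint8
        off = np.ones((4, 4), dtype=bool)
        off[1, 2] = False
        assert (gray[off] == 0).all()

    def test_white_frame_maps_to_us_ceiling(self):
        frame = np.full((3, 3, 3), 255, dtype=np.uint8)
        assert (cs.rgb_to_gray(frame) == 250).all()

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(FormatError):
            cs.rgb_to_gray(np.zeros((3, 3, 4)))
        with pytest.raises(FormatError):
            cs.rgb_to_gray(np.zeros((3, 3)))

    def test_luma_weights(self):
        # pure green is brighter than pure red is brighter than pure blue
        frames = [np.zeros((1, 1, 3), dtype=np.uint8) for _ in range(3)]
        for i, f in enumerate(frames):
            f[0, 0, i] = 255
        r, g, b = (cs.rgb_to_gray(f)[0, 0] for f in frames)
        assert g > r > b


class TestZeroOutsideRoi:
    def test_full_slice_region_is_identity(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        region = {"type": "rect", "coords": [0, 0, 4, 4]}
        np.testing.assert_array_equal(cs.zero_outside_roi(img, region), img)

    def test_empty_region_zeroes_everything(self):
        img = np.full((4, 4), 7, dtype=np.uint8)
        region = {"type": "rect", "coords": [2, 2, 2, 2]}
        assert cs.zero_outside_roi(img, region).sum() == 0

    def test_rect_keeps_exactly_the_inside(self):
        img = np.full((4, 4), 200, dtype=np.uint8)
        region = {"type": "rect", "coords": [1, 1, 3, 3]}
        out = cs.zero_outside_roi(img, region)
        assert (out == 200).sum() == 4
        assert (out == 0).sum() == 12
        assert (out[1:3, 1:3] == 200).all()

    def test_out_of_bounds_region_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(GeometryError):
            cs.zero_outside_roi(img, {"type": "rect", "coords": [0, 0, 5, 4]})
        with pytest.raises(GeometryError):
            cs.zero_outside_roi(img, {"type": "polygon", "coords": [[0, 0], [0, 10], [10, 10]]})

    @given(
        img=arrays(np.uint8, (6, 6), elements=st.integers(0, 250)),
        r0=st.integers(0, 5),
        c0=st.integers(0, 5),
        dr=st.integers(0, 5),
        dc=st.integers(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, img, r0, c0, dr, dc):
        region = {"type": "rect", "coords": [r0, c0, min(r0 + dr, 6), min(c0 + dc, 6)]}
        once = cs.zero_outside_roi(img, region)
        np.testing.assert_array_equal(cs.zero_outside_roi(once, region), once)

    def test_polygon_region(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        region = {"type": "polygon", "coords": [[0, 0], [0, 8], [8, 8], [8, 0]]}
        np.testing.assert_array_equal(cs.zero_outside_roi(img, region), img)


class TestSelectCalciumMask:
    def test_inclusive_threshold_enumeration(self):
        sl = np.array([[0, 129, 130], [250, 10, 140], [0, 0, 0]])
        mask = cs.select_calcium_mask(sl, 130)
        assert mask.sum() == 3
        assert mask[0, 2] and mask[1, 0] and mask[1, 2]

    def test_all_below_threshold(self):
        assert not cs.select_calcium_mask(np.full((3, 3), 129), 130).any()

    def test_threshold_at_range_minimum_selects_all(self):
        assert cs.select_calcium_mask(np.zeros((3, 3)), 0).all()

    @given(
        img=arrays(np.uint8, (16, 16), elements=st.integers(0, 250)),
        threshold=st.integers(0, 250),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_per_pixel_loop_oracle(self, img, threshold):
        mask = cs.select_calcium_mask(img, threshold)
        oracle = np.zeros_like(mask)
        for i in range(16):
            for j in range(16):
                oracle[i, j] = img[i, j] >= threshold
        np.testing.assert_array_equal(mask, oracle)

    @given(
        img=arrays(np.uint8, (8, 8), elements=st.integers(0, 250)),
        t1=st.integers(0, 250),
        t2=st.integers(0, 250),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_grows_mask(self, img, t1, t2):
        lo, hi = sorted((t1, t2))
        assert cs.select_calcium_mask(img, hi).sum() <= cs.select_calcium_mask(img, lo).sum()


class TestMeasureSlice:
    def test_area_is_count_times_pixel_area(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :3] = True
        m = cs.measure_slice(mask, np.full((4, 4), 5), (0.1, 0.1))
        assert m.area_calcium_mm2 == pytest.approx(0.03)

    def test_empty_mask_gives_zero_area_and_pv_max(self):
        m = cs.measure_slice(np.zeros((3, 3), dtype=bool), np.full((3, 3), 9), (1, 1))
        assert m.area_calcium_mm2 == 0 and m.pv_max == 0 and m.score == 0

    def test_pv_max_over_selected_pixels(self):
        img = np.array([[130, 250, 140], [0, 0, 0], [0, 0, 0]])
        mask = img > 0
        assert cs.measure_slice(mask, img, (1, 1)).pv_max == 250

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            cs.measure_slice(np.zeros((2, 2), dtype=bool), np.zeros((3, 3)), (1, 1))

    @given(img=arrays(np.uint8, (8, 8), elements=st.integers(0, 250)))
    @settings(max_examples=30, deadline=None)
    def test_area_additive_pv_max_is_union_max(self, img):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4] = img[:4] > 100
        b[4:] = img[4:] > 100
        ma = cs.measure_slice(a, img, (1, 1))
        mb = cs.measure_slice(b, img, (1, 1))
        mu = cs.measure_slice(a | b, img, (1, 1))
        assert mu.area_calcium_mm2 == pytest.approx(ma.area_calcium_mm2 + mb.area_calcium_mm2)
        assert mu.pv_max == max(ma.pv_max, mb.pv_max)


class TestDomainTypes:
    def test_us_stack_rejects_out_of_range_pixels(self):
        with pytest.raises(cs.ValidationError):
            cs.ImageStack(
                pixels=np.full((1, 2, 2), 251, dtype=np.uint16),
                pixel_spacing_mm=(0.1, 0.1),
                slice_spacing_mm=1.0,
                modality="US",
            )

    def test_spacing_must_be_positive(self):
        with pytest.raises(cs.ValidationError):
            cs.ImageStack(
                pixels=np.zeros((1, 2, 2), dtype=np.uint8),
                pixel_spacing_mm=(0.1, 0.0),
                slice_spacing_mm=1.0,
                modality="US",
            )

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.CTCalibration(pv_water=100, pv_air=100)

    def test_empty_selection_invariant_enforced(self):
        with pytest.raises(cs.ValidationError):
            cs.SliceMeasurement(slice_index=0, area_calcium_mm2=0.0, pv_max=5.0, score=0.0)
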