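"""Measurement chain: hue shifting, classification, calibration, areas."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from hypothesis.extra import numpy as st_np

import ferncover as fc
from ferncover import imaging as im
from ferncover import synthgen as sg

FIXTURE_SCALE = 900.0


def _pixel(r, g, b):
    return np.array([[[r, g, b]]], dtype=np.uint8)


def _hsv_to_rgb8(h_deg, s, v):
    """Independent closed-form HSV reference via colorsys."""
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360) / 360.0, s, v)
    return np.array([round(r * 255), round(g * 255), round(b * 255)], dtype=np.uint8)


class TestShiftHueBand:
    def test_pure_yellow_moves_ten_degrees(self):
        img = _pixel(255, 255, 0)  # hue 60, S=1, V=1
        out = im.shift_hue_band(img, im.HueShiftSpec((30, 90), 10, "none"))
        assert tuple(out[0, 0]) == tuple(_hsv_to_rgb8(70, 1.0, 1.0))

    def test_out_of_band_hue_unchanged(self):
        blue = _pixel(0, 0, 255)  # hue 240
        out = im.shift_hue_band(blue)
        assert np.array_equal(out, blue)

    def test_gray_pixel_unchanged(self):
        gray = _pixel(128, 128, 128)  # saturation 0: hue undefined
        assert np.array_equal(im.shift_hue_band(gray), gray)

    def test_preserves_saturation_value(self):
        img = _pixel(200, 180, 40)  # yellowish, in band
        out = im.shift_hue_band(img)
        h0, s0, v0 = colorsys.rgb_to_hsv(*(img[0, 0] / 255.0))
        h1, s1, v1 = colorsys.rgb_to_hsv(*(out[0, 0] / 255.0))
        assert s1 == pytest.approx(s0, abs=0.01)
        assert v1 == pytest.approx(v0, abs=0.01)
        assert (h1 - h0) * 360 == pytest.approx(10, abs=0.5)

    def test_idempotent_outside_band_after_shift(self):
        """Pixels shifted beyond the band ceiling are stable under re-application."""
        img = _pixel(150, 200, 40)  # hue ~ 79: shifts to 89, then out of reach
        once = im.shift_hue_band(img, im.HueShiftSpec((30, 90), 25))
        twice = im.shift_hue_band(once, im.HueShiftSpec((30, 90), 25))
        assert np.array_equal(once, twice)

    def test_cosine_falloff_tapers_at_edges(self):
        spec = im.HueShiftSpec((30, 90), 10, "cosine")
        center = _pixel(*_hsv_to_rgb8(60, 0.8, 0.8))
        edge = _pixel(*_hsv_to_rgb8(31, 0.8, 0.8))
        dc = colorsys.rgb_to_hsv(*(im.shift_hue_band(center, spec)[0, 0] / 255.0))[0]
        de = colorsys.rgb_to_hsv(*(im.shift_hue_band(edge, spec)[0, 0] / 255.0))[0]
        assert dc * 360 - 60 == pytest.approx(10, abs=0.5)
        assert de * 360 - 31 < 2.0

    @given(
        st_np.arrays(np.uint8, (6, 7, 3), elements=st_h.integers(0, 255)),
    )
    @settings(max_examples=25, deadline=None)
    def test_shape_preserved_and_dims_unchanged(self, img):
        out = im.shift_hue_band(img)
        assert out.shape == img.shape and out.dtype == np.uint8


class TestClassifyColor:
    @given(
        st_np.arrays(np.uint8, (32, 32, 3), elements=st_h.integers(0, 255)),
        st_h.sampled_from(["green", "red"]),
        st_h.integers(0, 30),
        st_h.sampled_from([1, 2, 3]),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_naive_oracle(self, img, target, excess, factor):
        rule = im.ColorRule(target, excess, 40, factor)
        fast = im.classify_color(img, rule)
        slow = im.naive_classify(img, rule)
        assert np.array_equal(fast.mask, slow)
        assert fast.count == int(slow.sum())

    def test_counts_monotone_in_min_excess(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        counts = [
            im.classify_color(img, im.ColorRule("green", e, 40, 2)).count
            for e in (0, 5, 10, 20, 40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_red_square_green_vs_red(self):
        img = sg.render_calibration_square(100.0, 100.0, seed=0)
        assert im.classify_color(img, im.ColorRule("green", 10, 40, 1)).count == 0
        assert im.classify_color(img, im.ColorRule("red", 10, 40, 1)).count == 10000

    def test_count_in_downsampled_pixels(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:, :, 1] = 200  # all green
        assert im.classify_color(img, im.ColorRule("green", 10, 40, 2)).count == 16
        assert im.classify_color(img, im.ColorRule("green", 10, 40, 1)).count == 64


class TestCalibrate:
    def test_paper_scale_constant(self):
        squares = [sg.render_calibration_square(100.0, 2190.0, seed=i) for i in range(3)]
        cal = im.calibrate(squares, 100.0, im.ColorRule("red", 10, 40, 1))
        assert cal.px_per_mm2 == pytest.approx(2190.0, rel=0.01)

    def test_mean_of_observations(self):
        # two synthetic squares straddling the nominal count average out
        imgs = []
        for count in (9900, 10100):
            img = np.full((120, 120, 3), 235, dtype=np.uint8)
            side = int(np.sqrt(count))
            img[:side, :side] = (190, 45, 40)
            extra = count - side * side
            if extra:
                img[side, :extra] = (190, 45, 40)
            imgs.append(img)
        cal = im.calibrate(imgs, 100.0, im.ColorRule("red", 10, 40, 1))
        assert cal.px_per_mm2 == pytest.approx(100.0)
        assert cal.n_observations == 2

    def test_zero_red_rejected(self):
        blank = np.full((32, 32, 3), 235, dtype=np.uint8)
        with pytest.raises(ValueError, match="no red"):
            im.calibrate([blank], 100.0, im.ColorRule("red", 10, 40, 1))


class TestPixelsToArea:
    @pytest.mark.parametrize(
        "count,px_per_mm2,expected", [(2190, 2190.0, 1.0), (0, 2190.0, 0.0), (21900, 2190.0, 10.0)]
    )
    def test_conversion(self, count, px_per_mm2, expected):
        cal = im.Calibration(px_per_mm2)
        assert im.pixels_to_area(count, cal) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            im.pixels_to_area(-1, im.Calibration(100.0))


class TestMeasureWell:
    def test_empty_well_measures_zero(self, calibration):
        ps = []
        img, _ = sg.render_well_image(ps, {}, px_per_mm2=FIXTURE_SCALE, seed=0)
        obs = im.measure_well(img, calibration)
        assert obs.pixels == 0 and obs.area_mm2 == 0.0

    def test_round_trip_recovers_truth(self, mixture_well, calibration):
        truth_total = sum(mixture_well["areas"].values())
        obs = im.measure_well(mixture_well["image"], calibration)
        assert obs.area_mm2 == pytest.approx(truth_total, rel=0.025)

    def test_downsample_scale_consistency(self, mixture_well):
        """Areas agree between 1x and 2x processing with matched calibration."""
        squares = [sg.render_calibration_square(100.0, FIXTURE_SCALE, seed=i) for i in range(3)]
        img = mixture_well["image"]
        areas = {}
        for f in (1, 2):
            cal = im.calibrate(squares, 100.0, im.ColorRule("red", 10, 40, f))
            obs = im.measure_well(
                img, cal, green_rule=im.ColorRule("green", 20, 40, f)
            )
            areas[f] = obs.area_mm2
        assert areas[1] == pytest.approx(areas[2], rel=0.03)

    def test_hue_shift_rescues_yellow_tissue(self, calibration):
        """A gametophyte-sized patch of yellow tissue (hue < 60) is invisible
        to the green rule until the yellow-band shift is applied."""
        img = np.full((60, 60, 3), sg.AppearanceParams().background_rgb, dtype=np.uint8)
        patch = np.zeros((60, 60), dtype=bool)
        patch[20:40, 20:40] = True
        yellow = np.array(
            [colorsys.hsv_to_rgb(59 / 360, 0.85, 0.8)]
        ).ravel() * 255
        img[patch] = yellow.astype(np.uint8)
        rule = im.ColorRule("green", 20, 40, 1)
        before = im.classify_color(img, rule).count
        after = im.classify_color(
            im.shift_hue_band(img, im.HueShiftSpec((30, 90), 10)), rule
        ).count
        # +10 deg moves hue 59 -> 69: green channel takes over
        assert before == 0
        assert after == 400

    def test_area_scale_invariance(self):
        """Doubling raster resolution and recalibrating leaves areas unchanged."""
        ps = [fc.SporePlacement(1, "1A", 1, "F", 0.0, 0.0)]
        areas = {}
        for scale in (400.0, 1600.0):
            squares = [sg.render_calibration_square(100.0, scale, seed=i) for i in range(3)]
            cal = im.calibrate(squares, 100.0, im.DEFAULT_RED_RULE)
            img, _ = sg.render_well_image(ps, {1: 1.5}, px_per_mm2=scale, seed=4)
            areas[scale] = im.measure_well(img, cal).area_mm2
        assert areas[400.0] == pytest.approx(areas[1600.0], rel=0.02)


def test_jpeg_recode_is_nearly_lossless_for_classification(mixture_well, calibration):
    plain = im.measure_well(mixture_well["image"], calibration)
    dialect = im.measure_well(mixture_well["image"], calibration, jpeg_dialect=True)
    assert dialect.pixels == pytest.approx(plain.pixels, rel=0.03)
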