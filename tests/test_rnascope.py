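import numpy as np
import pytest

from valveflow.pipeline import default_spot_spec, quantify_spot_image
from valveflow.rnascope import (DotCalibration, RoiMeasurement,
                                background_level, dots_in_roi, measure_roi,
                                mean_dot_intensity, quantify_slices)
from valveflow.synthetic import generate_spot_image


def rect(x, y, w, h):
    return np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]], float)


class TestMeasureRoi:
    def test_uniform_image(self):
        img = np.full((20, 30), 7.0)
        m = measure_roi(img, rect(0, 0, 10, 8))
        assert m.area == 80          # half-open: left/top edges in
        assert m.integrated_intensity == pytest.approx(7.0 * 80)

    def test_half_open_tiling_additivity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (20, 20))
        whole = measure_roi(img, rect(2, 2, 12, 12))
        left = measure_roi(img, rect(2, 2, 6, 12))
        right = measure_roi(img, rect(8, 2, 6, 12))
        assert left.area + right.area == whole.area
        assert left.integrated_intensity + right.integrated_intensity == \
            pytest.approx(whole.integrated_intensity, rel=1e-12)

    def test_polygon_outside_image_raises(self):
        with pytest.raises(ValueError):
            measure_roi(np.zeros((10, 10)), rect(100, 100, 5, 5))


class TestBackgroundLevel:
    def test_uniform_value(self):
        img = np.full((50, 50), 3.5)
        assert background_level(measure_roi(img, rect(5, 5, 20, 20))) == \
            pytest.approx(3.5)

    def test_intensive_under_roi_growth(self):
        img = np.full((60, 60), 2.0)
        small = background_level(measure_roi(img, rect(5, 5, 10, 10)))
        large = background_level(measure_roi(img, rect(5, 5, 40, 40)))
        assert small == pytest.approx(large, rel=1e-12)

    def test_noisy_estimate_standard_error(self):
        rng = np.random.default_rng(1)
        b, sd, n_side = 50.0, 4.0, 100
        img = b + rng.normal(0, sd, (n_side, n_side))
        est = background_level(measure_roi(img, rect(0, 0, n_side, n_side)))
        assert abs(est - b) < 2 * sd / n_side  # 2 se of the mean over n^2 px


class TestMeanDotIntensity:
    def _bg(self, level=2.0):
        return RoiMeasurement("bg", integrated_intensity=level * 100.0,
                              area=100.0)

    def test_identical_corrected_dots(self):
        cal = DotCalibration(dots=[(50.0 + 2.0 * 9.0, 9.0)] * 20,
                             background_roi=self._bg())
        assert mean_dot_intensity(cal) == pytest.approx(50.0, rel=1e-12)

    def test_zero_background_arithmetic_mean(self):
        cal = DotCalibration(dots=[(10.0, 4.0), (30.0, 4.0)],
                             background_roi=RoiMeasurement("bg", 0.0, 100.0))
        assert mean_dot_intensity(cal) == pytest.approx(20.0)

    def test_dim_dots_raise(self):
        cal = DotCalibration(dots=[(5.0, 9.0)], background_roi=self._bg())
        with pytest.raises(ValueError, match="not brighter"):
            mean_dot_intensity(cal)

    def test_gaussian_integral_recovery(self):
        # calibration from measured disks around synthetic isolated dots
        spec = default_spot_spec((20,), seed=9)
        spot = generate_spot_image(spec)
        bg_roi = measure_roi(spot.image, spot.roi_polygons["background"])
        bg = background_level(bg_roi)
        dots = []
        for row in spot.ledger.itertuples(index=False):
            r = 3 * spec.dot_sigma
            m = measure_roi(spot.image, rect(row.x_px - r, row.y_px - r,
                                             2 * r, 2 * r))
            dots.append((m.integrated_intensity, m.area))
        cal = DotCalibration(dots=dots, background_roi=bg_roi)
        expected = spec.dot_amplitude * 2 * np.pi * spec.dot_sigma ** 2
        assert mean_dot_intensity(cal) == pytest.approx(expected, rel=0.05)


class TestDotsInRoi:
    def test_pure_background_near_zero(self):
        # region_1 carries the calibration dots; region_0 is dot-free
        spec = default_spot_spec((0, 20), seed=4)
        spot = generate_spot_image(spec)
        res = quantify_spot_image(spot, spec)
        assert abs(res["region_0"].count) < 1.0

    def test_planted_count_recovered(self):
        counts = []
        for seed in range(5):
            spec = default_spot_spec((12,), seed=seed)
            spot = generate_spot_image(spec)
            counts.append(quantify_spot_image(spot, spec)["region_0"].count)
        assert np.all(np.abs(np.array(counts) - 12) <= 2.0)
        assert abs(np.mean(counts) - 12) <= 1.0

    def test_below_background_roi_negative_passthrough(self):
        spec = default_spot_spec((0, 20), seed=2, dim_offset=-2.0)
        spot = generate_spot_image(spec)
        res = quantify_spot_image(spot, spec)
        assert res["dim"].count < -5.0
        assert res["dim"].density == pytest.approx(
            res["dim"].count / res["dim"].area)

    def test_invalid_dot_mean(self):
        roi = RoiMeasurement("r", 100.0, 10.0)
        with pytest.raises(ValueError):
            dots_in_roi(roi, background=1.0, dot_mean=0.0)


class TestQuantifySlices:
    def _cal(self):
        bg = RoiMeasurement("bg", 50.0 * 400, 400.0)
        return DotCalibration(dots=[(1000.0 + 50.0 * 9, 9.0)] * 20,
                              background_roi=bg)

    def test_identical_slices_additivity(self):
        spec = default_spot_spec((12,), seed=6, )
        spot = generate_spot_image(spec)
        regions = {"region_0": spot.roi_polygons["region_0"]}
        bg_roi = measure_roi(spot.image, spot.roi_polygons["background"])
        bg = background_level(bg_roi)
        dots = [(r.integrated_intensity + bg * r.area_px2, r.area_px2)
                for r in spot.ledger.itertuples(index=False)]
        cal = DotCalibration(dots=dots, background_roi=bg_roi)
        single = quantify_slices([spot.image], regions, cal,
                                 n_slices_expected=1)
        triple = quantify_slices([spot.image] * 3, regions, cal)
        assert triple["region_0"].count == pytest.approx(
            3 * single["region_0"].count, rel=1e-9)

    def test_planted_two_region_recovery(self):
        spec = default_spot_spec((30, 90), seed=8)
        spot = generate_spot_image(spec)
        bg_roi = measure_roi(spot.image, spot.roi_polygons["background"])
        bg = background_level(bg_roi)
        dots = [(r.integrated_intensity + bg * r.area_px2, r.area_px2)
                for r in spot.ledger.head(20).itertuples(index=False)]
        cal = DotCalibration(dots=dots, background_roi=bg_roi)
        regions = {k: v for k, v in spot.roi_polygons.items()
                   if k.startswith("region")}
        res = quantify_slices([spot.image] * 3, regions, cal)
        assert res["region_0"].count == pytest.approx(90, rel=0.10)   # 3x30
        assert res["region_1"].count == pytest.approx(270, rel=0.10)  # 3x90

    def test_empty_region_list(self):
        assert quantify_slices([np.zeros((10, 10))] * 3, {}, self._cal()) == {}

    def test_wrong_slice_count_raises(self):
        with pytest.raises(ValueError, match="z-slices"):
            quantify_slices([np.zeros((10, 10))] * 2, {}, self._cal())

    def test_region_outside_slice_raises(self):
        regions = {"r": rect(100, 100, 5, 5)}
        with pytest.raises(ValueError):
            quantify_slices([np.full((10, 10), 60.0)] * 3, regions,
                            self._cal())


def test_count_invariant_under_global_rescaling():
    # scaling image, calibration and background together cancels exactly
    spec = default_spot_spec((12,), seed=3)
    spot = generate_spot_image(spec)

    def count(scale):
        img = scale * spot.image
        bg_roi = measure_roi(img, spot.roi_polygons["background"])
        bg = background_level(bg_roi)
        dots = [(scale * r.integrated_intensity + bg * r.area_px2,
                 r.area_px2)
                for r in spot.ledger.itertuples(index=False)]
        cal = DotCalibration(dots=dots, background_roi=bg_roi)
        roi = measure_roi(img, spot.roi_polygons["region_0"])
        return dots_in_roi(roi, bg, mean_dot_intensity(cal))[0]

    assert count(1.0) == pytest.approx(count(7.0), rel=1e-9)
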