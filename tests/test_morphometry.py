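"""Line scans, thresholds, void/gap areas and ring-width estimators."""

import math

import numpy as np
import pytest

from centmorph import (CalibratedImage, IntensityProfile, PolygonROI,
                       area_intensity, diameter_from_profiles, gap_area,
                       intensity_within_outline, line_scan, mt_ring_area,
                       pcm_threshold, ring_width_linescan,
                       ring_width_threshold, torus_threshold, void_area,
                       void_threshold)
from centmorph.errors import (EmptyRegionError, GeometryError, OpenRingError,
                              PeakDetectionError, ThresholdInversionError,
                              TruncatedPeakError)
from centmorph.morphometry import ThresholdMask
from centmorph.synthetic import RingSpec, _circle_roi, make_ring_image


def profile(values, spacing=0.05, width=1.0):
    values = np.asarray(values, float)
    n = len(values)
    pos = (np.arange(n) - (n - 1) / 2) * spacing
    return IntensityProfile(positions=pos, values=values, line_width=width)


class TestLineScan:
    def test_constant_field_flat_profile(self, constant_image):
        p = line_scan(constant_image, (31.5, 31.5), 17.0, 4.0, 1.0)
        assert np.allclose(p.values, 5.0)

    def test_vertical_stripe_plateau(self):
        px = np.zeros((64, 64))
        px[:, 20:31] = 10.0  # stripe 11 px wide = 1.1 um at 0.1 um/px
        img = CalibratedImage(px, 0.1)
        p = line_scan(img, (25.0, 32.0), 0.0, 4.0, 0.1)
        plateau = p.positions[p.values == 10.0]
        extent = plateau.max() - plateau.min()
        assert extent == pytest.approx(1.0, abs=0.1)  # 11 centers span 1.0 um

    def test_rotation_equivariance(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((72, 72)), 3)
        c = ((72 - 1) / 2, (72 - 1) / 2)
        p1 = line_scan(CalibratedImage(img, 0.1), c, 33.0, 4.0, 0.5)
        p2 = line_scan(CalibratedImage(np.rot90(img), 0.1), c, 33.0 - 90.0, 4.0, 0.5)
        assert np.allclose(p1.values, p2.values, atol=1e-6)

    def test_scan_exiting_raster_raises(self, constant_image):
        with pytest.raises(GeometryError):
            line_scan(constant_image, (31.5, 31.5), 0.0, 20.0, 1.0)


class TestDiameter:
    def test_constructed_triangular_peaks(self):
        pos_peaks = [-1.5, 1.5]
        xs = np.arange(-2.5, 2.51, 0.05)
        vals = np.zeros_like(xs)
        for c in pos_peaks:
            vals += np.clip(1 - np.abs(xs - c) / 0.3, 0, None)
        p = IntensityProfile(xs, vals, 1.0)
        d = diameter_from_profiles(p, p)
        assert d.d1 == pytest.approx(3.0, abs=1e-9)
        assert d.average == pytest.approx(3.0, abs=1e-9)

    def test_average_is_mean_of_d1_d2(self):
        xs = np.arange(-3.5, 3.51, 0.05)

        def two_peaks(c):
            v = np.zeros_like(xs)
            for s in (-c, c):
                v += np.clip(1 - np.abs(xs - s) / 0.3, 0, None)
            return IntensityProfile(xs, v, 1.0)

        d = diameter_from_profiles(two_peaks(1.5), two_peaks(2.5))
        assert (d.d1, d.d2) == (pytest.approx(3.0), pytest.approx(5.0))
        assert d.average == pytest.approx(4.0)

    @pytest.mark.parametrize("D", [2.0, 3.0, 4.0])
    def test_synthetic_annulus_within_one_pixel(self, D):
        img, truth = make_ring_image(RingSpec(diameter=D, width_param=0.4),
                                     image_size=128, pixel_size=0.1, seed=0)
        p1 = line_scan(img, truth["center"], 0.0, D + 2.0, 0.1)
        p2 = line_scan(img, truth["center"], 90.0, D + 2.0, 0.1)
        d = diameter_from_profiles(p1, p2)
        assert abs(d.average - D) <= 0.1

    def test_single_peak_raises_with_profile_dump(self):
        xs = np.arange(-2.0, 2.01, 0.05)
        vals = np.exp(-0.5 * ((xs - 1.0) / 0.2) ** 2)
        p = IntensityProfile(xs, vals, 1.0)
        with pytest.raises(PeakDetectionError) as exc:
            diameter_from_profiles(p, p)
        assert exc.value.profile is not None


class TestThresholds:
    def test_torus_formula(self):
        # torus pixels with min 10, mean 30, max 90 -> lower 20, upper 90
        px = np.full((32, 32), 1.0)
        ring = [10.0, 90.0, 20.0, 20.0, 20.0, 20.0]  # mean 30 over 6 values
        torus_pixels = [(5, 5), (5, 6), (5, 7), (6, 5), (6, 6), (6, 7)]
        for (r, c), v in zip(torus_pixels, ring):
            px[r, c] = v
        img = CalibratedImage(px, 1.0)
        outer = PolygonROI([[4.5, 4.5], [7.5, 4.5], [7.5, 6.5], [4.5, 6.5]],
                           kind="torus_outer")
        inner = PolygonROI([[0.1, 0.1], [0.3, 0.1], [0.3, 0.3]],
                           kind="torus_inner")
        tm = torus_threshold(img, outer, inner)
        assert tm.lower == pytest.approx(20.0)
        assert tm.upper == pytest.approx(90.0)

    def test_uniform_torus_fully_selected(self, constant_image):
        outer = PolygonROI([[10, 10], [40, 10], [40, 40], [10, 40]],
                           kind="torus_outer")
        inner = PolygonROI([[20, 20], [30, 20], [30, 30], [20, 30]],
                           kind="torus_inner")
        tm = torus_threshold(constant_image, outer, inner)
        torus = outer.contains_mask(constant_image.shape) & \
            ~inner.contains_mask(constant_image.shape)
        assert np.array_equal(tm.mask, torus)  # inclusive bounds keep all

    def test_mask_matches_brute_force(self):
        img, truth = make_ring_image(RingSpec(noise="poisson+gaussian"),
                                     image_size=128, pixel_size=0.05, seed=7)
        c = truth["center"]
        outer = _circle_roi(c, truth["r_outer"] / 0.05 + 4, "torus_outer")
        inner = _circle_roi(c, truth["r_inner"] / 0.05 - 4, "torus_inner")
        tm = torus_threshold(img, outer, inner)
        torus = outer.contains_mask(img.shape) & ~inner.contains_mask(img.shape)
        expected = torus & (img.pixels >= tm.lower) & (img.pixels <= tm.upper)
        assert np.array_equal(tm.mask, expected)

    def test_void_threshold_formula(self):
        px = np.full((32, 32), 1.0)
        px[5, 5:8] = [30.0, 90.0, 90.0]
        px[6, 5:8] = [30.0, 30.0, 0.0 + 30.0 * 0]  # last replaced below
        px[6, 7] = 0.0
        # choose region mean 30, max 90 -> lower 60
        region = [(5, 5), (5, 6), (5, 7), (6, 5), (6, 6), (6, 7)]
        vals = [30, 90, 30, 30, 0, 0]
        for (r, c), v in zip(region, vals):
            px[r, c] = v
        img = CalibratedImage(px, 1.0)
        roi = PolygonROI([[4.5, 4.5], [7.5, 4.5], [7.5, 6.5], [4.5, 6.5]],
                         kind="freehand")
        tm = void_threshold(img, roi)
        assert tm.lower == pytest.approx(60.0)
        assert tm.upper == pytest.approx(90.0)

    def test_pcm_formula_and_disk_selection(self):
        px = np.full((64, 64), 5.0)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (xx - 40) ** 2 + (yy - 40) ** 2 <= 8 ** 2
        px[disk] = 100.0
        img = CalibratedImage(px, 0.1)
        bg = PolygonROI([[2, 2], [12, 2], [12, 12], [2, 12]], kind="background")
        tm = pcm_threshold(img, bg)
        assert tm.lower == pytest.approx(10.0)  # mean 5 + max 5
        assert np.array_equal(tm.mask, disk)

    def test_threshold_inversion(self):
        px = np.full((32, 32), 50.0)
        px[5:10, 5:10] = 60.0  # "object" barely above a bright background
        img = CalibratedImage(px, 1.0)
        bg = PolygonROI([[15, 15], [30, 15], [30, 30], [15, 30]],
                        kind="background")
        with pytest.raises(ThresholdInversionError):
            pcm_threshold(img, bg)


class TestVoidArea:
    @staticmethod
    def annulus_mask(n, r_in, r_out, center=None):
        c = (n - 1) / 2 if center is None else center
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - c, yy - c)
        return (r >= r_in) & (r <= r_out)

    def test_analytic_circle_area(self):
        for r in (10, 15, 20):
            mask = self.annulus_mask(64, r, r + 5)
            tm = ThresholdMask(mask, 0, 1, "torus_mean_min")
            a = void_area(tm, (31.5, 31.5), 1.0)
            assert a == pytest.approx(math.pi * r ** 2, rel=0.02)

    def test_pixel_counting_oracle(self):
        mask = self.annulus_mask(32, 5, 16, center=15.5)
        tm = ThresholdMask(mask, 0, 1, "torus_mean_min")
        a = void_area(tm, (15.5, 15.5), 1.0)
        # independent oracle: BFS flood fill from the center
        seen = np.zeros_like(mask)
        stack = [(15, 15)]
        while stack:
            r, c = stack.pop()
            if not (0 <= r < 32 and 0 <= c < 32) or seen[r, c] or mask[r, c]:
                continue
            seen[r, c] = True
            stack += [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
        assert a == seen.sum()
        assert a == pytest.approx(math.pi * 25, rel=0.05)

    def test_broken_ring_raises(self):
        mask = self.annulus_mask(64, 20, 25)
        yy, xx = np.mgrid[0:64, 0:64]
        wedge = (np.degrees(np.arctan2(yy - 31.5, xx - 31.5)) % 360) < 90
        mask[wedge] = False
        tm = ThresholdMask(mask, 0, 1, "torus_mean_min")
        with pytest.raises(OpenRingError):
            void_area(tm, (31.5, 31.5), 1.0)


class TestAreaIntensity:
    def test_enumerable(self):
        px = np.zeros((16, 16))
        px[3, 3:13] = 7.0
        img = CalibratedImage(px, 1.0)
        mask = px > 0
        ai = area_intensity(mask, img)
        assert (ai.area, ai.total_intensity, ai.density) == (10.0, 70.0, 7.0)

    def test_intensity_linearity(self, rng):
        px = rng.uniform(1, 50, (16, 16))
        mask = rng.random((16, 16)) > 0.5
        a1 = area_intensity(mask, CalibratedImage(px, 0.5))
        a2 = area_intensity(mask, CalibratedImage(2 * px, 0.5))
        assert a2.total_intensity == pytest.approx(2 * a1.total_intensity)
        assert a2.density == pytest.approx(2 * a1.density)
        assert a2.area == a1.area

    def test_exhaustive_oracle(self, rng):
        px = rng.uniform(0, 100, (24, 24))
        mask = rng.random((24, 24)) > 0.7
        img = CalibratedImage(px, 0.3)
        ai = area_intensity(mask, img)
        total = sum(px[r, c] for r in range(24) for c in range(24) if mask[r, c])
        assert ai.total_intensity == pytest.approx(total, rel=1e-12)
        assert ai.area == pytest.approx(mask.sum() * 0.09)

    def test_empty_mask_raises(self, constant_image):
        with pytest.raises(EmptyRegionError):
            area_intensity(np.zeros((64, 64), bool), constant_image)


class TestIntensityWithinOutline:
    def test_constant_region(self):
        px = np.full((32, 32), 3.0)
        img = CalibratedImage(px, 1.0)
        roi = PolygonROI([[-0.4, -0.4], [4.4, -0.4], [4.4, 4.4], [-0.4, 4.4]],
                         kind="freehand")
        ai = intensity_within_outline(roi, img)
        assert ai.total_intensity == 25 * 3.0

    def test_zero_outside_signal(self):
        px = np.zeros((32, 32))
        px[20:30, 20:30] = 50.0
        img = CalibratedImage(px, 1.0)
        roi = PolygonROI([[1, 1], [8, 1], [8, 8], [1, 8]], kind="freehand")
        assert intensity_within_outline(roi, img).total_intensity == 0.0

    def test_matches_pixel_oracle(self, random_image, irregular_roi):
        from conftest import brute_force_region_pixels

        ai = intensity_within_outline(irregular_roi, random_image)
        mask = brute_force_region_pixels(random_image.shape,
                                         irregular_roi.vertices)
        assert ai.total_intensity == pytest.approx(
            random_image.pixels[mask].sum(), rel=1e-12)


class TestMTRingArea:
    def _scene(self):
        spec = RingSpec(diameter=2.5, width_param=0.5)
        img, truth = make_ring_image(spec, image_size=160, pixel_size=0.05,
                                     seed=0)
        c = truth["center"]
        outer = _circle_roi(c, truth["r_outer"] / 0.05 + 4, "torus_outer")
        inner = _circle_roi(c, truth["r_inner"] / 0.05 - 4, "torus_inner")
        return img, truth, outer, inner

    def test_no_exclusion_matches_outer_disk(self):
        img, truth, outer, inner = self._scene()
        area = mt_ring_area(img, outer, inner)
        assert area == pytest.approx(math.pi * truth["r_outer"] ** 2, rel=0.03)

    def test_wedge_exclusion_convex_closure(self):
        img, truth, outer, inner = self._scene()
        c = truth["center"]
        # wedge covering ~60 degrees of the ring
        wedge = PolygonROI([[c[0], c[1]],
                            [c[0] + 70, c[1] - 35], [c[0] + 70, c[1] + 35]],
                           kind="spindle_exclusion")
        area = mt_ring_area(img, outer, inner, spindle_exclusion=wedge)
        assert area == pytest.approx(math.pi * truth["r_outer"] ** 2, rel=0.03)

    def test_total_exclusion_raises(self):
        img, truth, outer, inner = self._scene()
        everything = PolygonROI([[0, 0], [159, 0], [159, 159], [0, 159]],
                                kind="spindle_exclusion")
        with pytest.raises(EmptyRegionError):
            mt_ring_area(img, outer, inner, spindle_exclusion=everything)


class TestRingWidth:
    def test_exact_circles(self):
        r = ring_width_threshold(4 * math.pi, math.pi)
        assert (r.R1, r.R2) == (pytest.approx(2.0), pytest.approx(1.0))
        assert r.width_threshold == pytest.approx(1.0)

    def test_degenerate_equal_areas(self):
        assert ring_width_threshold(5.0, 5.0).width_threshold == 0.0

    def test_argument_order_error(self):
        with pytest.raises(ValueError):
            ring_width_threshold(1.0, 2.0)

    def test_rasterized_annulus(self):
        # inner radius 1.0 um, outer 1.5 um at 0.05 um/px
        n = 160
        c = (n - 1) / 2 + 0.3
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - c, yy - c) * 0.05
        outer_area = float((r <= 1.5).sum()) * 0.05 ** 2
        void = float((r < 1.0).sum()) * 0.05 ** 2
        w = ring_width_threshold(outer_area, void)
        assert abs(w.width_threshold - 0.5) <= 0.05

    def test_rectangular_peak_width(self):
        xs = np.arange(-2.0, 2.01, 0.05)
        vals = np.where(np.abs(np.abs(xs) - 1.0) <= 0.25, 10.0, 0.0)
        p = IntensityProfile(xs, vals, 1.0)
        r = ring_width_linescan(p, p)
        assert len(r.peak_widths) == 4
        assert r.width_linescan == pytest.approx(0.5, abs=0.06)

    def test_gaussian_closed_form(self):
        # 90%-of-max width of a Gaussian: 2*sigma*sqrt(2 ln(10/9))
        sigma = 0.3
        xs = np.arange(-3.0, 3.001, 0.01)
        vals = (np.exp(-0.5 * ((xs - 1.2) / sigma) ** 2)
                + np.exp(-0.5 * ((xs + 1.2) / sigma) ** 2))
        p = IntensityProfile(xs, vals, 1.0)
        r = ring_width_linescan(p, p)
        expected = 2 * sigma * math.sqrt(2 * math.log(10 / 9))
        assert r.width_linescan == pytest.approx(expected, abs=0.01)

    def test_four_identical_peaks_average(self):
        xs = np.arange(-2.0, 2.01, 0.05)
        vals = np.where(np.abs(np.abs(xs) - 1.0) <= 0.25, 10.0, 0.0)
        p = IntensityProfile(xs, vals, 1.0)
        r = ring_width_linescan(p, p)
        assert r.width_linescan == pytest.approx(r.peak_widths[0])

    def test_truncated_peak_raises(self):
        xs = np.arange(-2.0, 2.01, 0.05)
        # left peak: clean triangle; right peak: descends so slowly on its
        # right flank that the 90% level is never crossed before the edge
        vals = np.clip(10 * (1 - np.abs(xs + 1.0) / 0.3), 0, None)
        right = xs >= 0.4
        vals[right] = np.where(xs[right] < 1.0,
                               10 * (xs[right] - 0.4) / 0.6,
                               10 - 0.2 * (xs[right] - 1.0))
        p = IntensityProfile(xs, vals, 1.0)
        with pytest.raises(TruncatedPeakError):
            ring_width_linescan(p, p)


class TestGapArea:
    @pytest.mark.parametrize("void,pcm,expected,overlap", [
        (10.0, 7.0, 3.0, False),
        (5.0, 5.0, 0.0, False),
        (4.0, 6.0, -2.0, True),
    ])
    def test_gap_arithmetic(self, void, pcm, expected, overlap):
        g = gap_area(void, pcm)
        assert g.gap == expected
        assert g.overlap is overlap

    def test_antisymmetry(self):
        assert gap_area(7.0, 3.0).gap == -gap_area(3.0, 7.0).gap
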