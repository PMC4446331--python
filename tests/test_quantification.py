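"""Density rendering and the organization metrics."""

import math

import numpy as np
import pytest

import filasim as fs
from filasim.patterns import Rect
from filasim.quantify import DensityImage

from conftest import free_world


def segment_world(segments, origins=None):
    """World of straight 2-vertex fibers from a list of (start, end)."""
    return fs.World.from_fibers([np.array([a, b]) for a, b in segments],
                                origins=origins)


class TestRenderDensity:
    def test_intensity_linear_in_length(self):
        w1 = segment_world([([0.0, 0.0], [1.0, 0.0])])
        w2 = segment_world([([0.0, 0.0], [2.0, 0.0])])
        ext = (-1, 3, -1, 1)
        i1 = fs.render_density(w1, 0.1, extent=ext).total
        i2 = fs.render_density(w2, 0.1, extent=ext).total
        assert i1 == pytest.approx(i2 / 2, rel=1e-9)

    def test_rotation_invariance_of_total_intensity(self):
        L = 2.0
        w_axis = segment_world([([0.0, 0.0], [L, 0.0])])
        w_diag = segment_world([([0.0, 0.0], [L / math.sqrt(2), L / math.sqrt(2)])])
        ext = (-1, 3, -1, 3)
        ia = fs.render_density(w_axis, 0.1, extent=ext).total
        ib = fs.render_density(w_diag, 0.1, extent=ext).total
        assert abs(ia - ib) / ia < 0.01

    def test_total_intensity_equals_total_fiber_length(self):
        rng = np.random.default_rng(2)
        fibs = [np.cumsum(rng.normal(0, 0.2, (12, 2)), axis=0) for _ in range(5)]
        w = fs.World.from_fibers(fibs)
        total_len = sum(np.linalg.norm(np.diff(f, axis=0), axis=1).sum()
                        for f in fibs)
        img = fs.render_density(w, 0.1, pad=3.0)
        assert img.total == pytest.approx(total_len, rel=0.01)

    def test_blur_conserves_intensity(self):
        w = segment_world([([0.0, 0.0], [1.0, 0.0])])
        ext = (-5, 6, -5, 5)
        i0 = fs.render_density(w, 0.1, blur_sigma=0.0, extent=ext).total
        i1 = fs.render_density(w, 0.1, blur_sigma=0.2, extent=ext).total
        assert abs(i1 - i0) / i0 < 1e-6

    def test_empty_world_renders_zero(self):
        w = fs.World.from_fibers([np.array([[50.0, 50.0], [50.2, 50.0]])])
        img = fs.render_density(w, 0.1, extent=(-1, 1, -1, 1))
        assert img.total == 0.0

    def test_rejects_bad_pixel_size(self):
        with pytest.raises(ValueError):
            fs.render_density(segment_world([([0, 0], [1, 0])]), 0.0)


def make_image(values, pixel_size=0.1, origin=None):
    values = np.asarray(values, float)
    ny, nx = values.shape
    if origin is None:  # centered
        origin = (-nx * pixel_size / 2 + pixel_size / 2,
                  -ny * pixel_size / 2 + pixel_size / 2)
    return DensityImage(pixel_size=pixel_size, values=values, origin=origin)


class TestCornerIntensityRatio:
    bar = Rect((0.0, 0.0), 8.0, 1.0)

    def test_uniform_image_gives_one(self):
        img = make_image(np.ones((140, 160)))
        assert fs.corner_intensity_ratio(img, self.bar) == pytest.approx(1.0)

    def test_axis_concentrated_image_gives_zero(self):
        v = np.zeros((140, 160))
        v[68:72, :] = 5.0   # bright horizontal band through the bar axis
        img = make_image(v)
        assert fs.corner_intensity_ratio(img, self.bar) == pytest.approx(0.0)

    def test_constructed_grid_arithmetic(self):
        # corner boxes forced to intensity 2 on a mean-4 image -> I_c = 0.5;
        # box masks recomputed here from the same geometric definition
        ps = 0.1
        v = np.full((140, 160), 4.0)
        img = make_image(v, ps)
        nbox = 0
        for su in (-1, 1):
            for sv in (-1, 1):
                cx, cy = su * (4.0 + 1.0), sv * (0.5 + 1.0)
                px = (cx - img.origin[0]) / ps
                py = (cy - img.origin[1]) / ps
                x0, x1 = int(round(px - 10)), int(round(px + 10))
                y0, y1 = int(round(py - 10)), int(round(py + 10))
                v[y0:y1, x0:x1] = 2.0
                nbox += (x1 - x0) * (y1 - y0)
        # restore the global mean to exactly 4
        rest = v != 2.0
        v[rest] += (4.0 * v.size - v.sum()) / rest.sum()
        assert fs.corner_intensity_ratio(img, self.bar, corner_box=2.0) == \
            pytest.approx(0.5, abs=1e-9)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            fs.corner_intensity_ratio(make_image(np.zeros((140, 160))), self.bar)


class TestEllipseIntensityDeviation:
    def test_constant_image_gives_zero(self):
        img = make_image(np.full((200, 200), 3.0))
        assert fs.ellipse_intensity_deviation(img, (0, 0), (5, 3)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_bundles_beat_spread_intensity(self):
        ny = nx = 200
        bundled = np.zeros((ny, nx))
        bundled[:, 95:105] = 10.0          # two crossings of the ellipse
        spread = np.full((ny, nx), bundled.mean())
        ib = fs.ellipse_intensity_deviation(make_image(bundled), (0, 0), (6, 6))
        is_ = fs.ellipse_intensity_deviation(make_image(spread), (0, 0), (6, 6))
        assert ib > is_

    def test_sinusoidal_profile_matches_analytic_std(self):
        # circular "ellipse": intensity 1 + a*cos(2 phi) sampled uniformly
        # in arc length == uniformly in phi -> normalized std = a/sqrt(2)
        ps = 0.05
        n = 400
        yy, xx = np.mgrid[0:n, 0:n]
        x = (xx - n / 2 + 0.5) * ps
        y = (yy - n / 2 + 0.5) * ps
        phi = np.arctan2(y, x)
        a = 0.4
        img = make_image(1.0 + a * np.cos(2 * phi), ps)
        got = fs.ellipse_intensity_deviation(img, (0, 0), (7, 7))
        assert got == pytest.approx(a / math.sqrt(2), rel=0.01)

    def test_degenerate_ellipse_rejected(self):
        with pytest.raises(ValueError):
            fs.ellipse_intensity_deviation(make_image(np.ones((10, 10))),
                                           (0, 0), (0.0, 1.0))


class TestMedianLineFractions:
    def _world_with_crossing_angles(self, angles_deg):
        segs = []
        for k, a in enumerate(angles_deg):
            d = np.array([math.cos(math.radians(a)), math.sin(math.radians(a))])
            c = np.array([0.0, 2.0 * k])
            segs.append((c - 0.3 * d, c + 0.3 * d))
        return segment_world(segs)

    def test_all_vertical_crossings_are_parallel(self):
        fr = fs.median_line_fractions(self._world_with_crossing_angles([90] * 7))
        assert fr["parallel"] == 1.0

    def test_45_degree_crossing_is_other(self):
        fr = fs.median_line_fractions(self._world_with_crossing_angles([45]))
        assert fr["other"] == 1.0

    def test_fractions_match_direct_counting(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(0, 180, 100)
        fr = fs.median_line_fractions(self._world_with_crossing_angles(angles))
        acute = np.minimum(angles % 180, 180 - angles % 180)
        par = np.count_nonzero(acute >= 70)
        anti = np.count_nonzero(acute <= 20)
        assert fr["n"] == 100
        assert fr["parallel"] == pytest.approx(par / 100)
        assert fr["antiparallel"] == pytest.approx(anti / 100)

    def test_no_crossings_flagged(self):
        w = segment_world([([1.0, 0.0], [2.0, 0.0])])
        fr = fs.median_line_fractions(w)
        assert fr["n"] == 0 and fr["parallel"] == 0.0


class TestMeetingAngles:
    def test_head_on_is_180(self):
        w = fs.generate_fixture("two_head_on")
        ang = fs.meeting_angles(w, contact_radius=0.25)
        assert len(ang) > 0
        assert np.allclose(ang, 180.0, atol=1e-9)

    def test_co_aligned_is_0(self):
        a = np.column_stack([np.arange(-3, 0.01, 0.2), np.zeros(16)])
        b = a + [0.0, 0.1]
        w = fs.World.from_fibers([a, b], origins=[0, 1])
        ang = fs.meeting_angles(w, contact_radius=0.2)
        assert len(ang) > 0
        assert np.allclose(ang, 0.0, atol=1e-9)

    def test_hand_constructed_tangent_angles(self):
        def ray(theta_deg, offset):
            d = np.array([math.cos(math.radians(theta_deg)),
                          math.sin(math.radians(theta_deg))])
            return np.vstack([offset - 0.2 * d, offset + 0.0 * d])
        w = fs.World.from_fibers([ray(30, np.zeros(2)), ray(170, [0.05, 0.0])],
                                 origins=[0, 1])
        ang = fs.meeting_angles(w, contact_radius=0.3)
        assert np.allclose(ang, 140.0, atol=1e-6)

    def test_symmetric_under_bar_exchange(self):
        w = fs.generate_fixture("two_head_on")
        a1 = fs.meeting_angles(w, contact_radius=0.25)
        w2 = fs.World.from_fibers([w.fiber_vertices(1), w.fiber_vertices(0)],
                                  origins=[1, 0])
        a2 = fs.meeting_angles(w2, contact_radius=0.25)
        assert np.allclose(np.sort(a1), np.sort(a2))


class TestRhoExt:
    def test_identical_measurements_give_zero(self):
        assert fs.rho_ext(2.0, 3.0, 2.0, 3.0) == 0.0

    def test_direct_arithmetic(self):
        assert fs.rho_ext(1.0, 3.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_zero_initial_intensity_rejected(self):
        with pytest.raises(ValueError):
            fs.rho_ext(0.0, 1.0, 1.0, 1.0)


class TestDistributionTests:
    def test_ks_identical_samples_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        D, p = fs.ks_test(x, x)
        assert D == 0.0

    def test_ks_shifted_integer_samples(self):
        # ECDF sup-distance of {1..5} vs {2..6} enumerated by hand: 0.2
        D, _ = fs.ks_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert D == pytest.approx(0.2)

    def test_spearman_perfect_inverse(self):
        rho, p = fs.spearman_trend([1, 2, 3, 4, 5], [10, 8, 6, 4, 2][::-1][::-1])
        assert rho == pytest.approx(-1.0)

    def test_spearman_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fs.spearman_trend([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_wilcoxon_detects_clear_offset(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.1, 30)
        _, p = fs.wilcoxon_vs_zero(x)
        assert p < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fs.ks_test([1.0], [2.0])


class TestMetricPurity:
    def test_metrics_are_pure_functions(self):
        w = fs.generate_fixture("two_head_on")
        a1 = fs.meeting_angles(w, contact_radius=0.25)
        a2 = fs.meeting_angles(w, contact_radius=0.25)
        assert np.array_equal(a1, a2)
        img1 = fs.render_density(w, 0.2, blur_sigma=0.1, extent=(-6, 6, -2, 2))
        img2 = fs.render_density(w, 0.2, blur_sigma=0.1, extent=(-6, 6, -2, 2))
        assert np.array_equal(img1.values, img2.values)
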