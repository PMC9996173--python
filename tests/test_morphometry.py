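"""Contour, centroid, polar decomposition and the minimum-diameter search."""

import math
import warnings

import numpy as np
import pytest

from coameter import (
    DiameterSearchParams,
    NoDiameterFound,
    NoLumenFound,
    PhantomSpec,
    ScaleCalibration,
    calibrate,
    centroid_of,
    extract_contour,
    find_min_diameter,
    generate_cross_section,
    measure,
    measure_mask,
    to_polar_quadrants,
)
from coameter.morphometry import Centroid, PolarContourPoint, moments

from oracles import min_centroid_chord


def disc_mask(radius: int, size: int = 0) -> np.ndarray:
    size = size or 2 * radius + 21
    ys, xs = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    return ((xs - c) ** 2 + (ys - c) ** 2 <= radius**2).astype(np.uint8)


class TestContour:
    def test_3x3_square_has_8_boundary_points(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        assert len(extract_contour(mask)) == 8

    def test_largest_component_wins(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[5:30, 5:25] = 1  # 500 px
        mask[40:48, 40:45] = 1  # 40 px
        contour = extract_contour(mask)
        assert contour[:, 0].max() < 30  # all points on the large blob

    def test_single_pixel_rejected(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 1
        with pytest.raises(NoLumenFound):
            extract_contour(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(NoLumenFound):
            extract_contour(np.zeros((5, 5), dtype=np.uint8))

    def test_boundary_points_lie_on_mask_edge(self):
        mask = disc_mask(15)
        contour = extract_contour(mask)
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask.astype(bool))
        for x, y in contour.astype(int):
            assert mask[y, x] == 1 and not interior[y, x]


class TestCentroid:
    def test_filled_square_centroid(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[0:11, 0:11] = 1  # pixels (0..10, 0..10)
        assert centroid_of(mask) == Centroid(5.0, 5.0)

    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3, 7] = 1  # (x=7, y=3)
        assert centroid_of(mask) == Centroid(7.0, 3.0)

    def test_right_triangle_near_continuous_centroid(self):
        # legs of 60 px on the axes; continuous centroid at legs/3
        n = 60
        ys, xs = np.mgrid[0:n, 0:n]
        mask = (xs + ys < n).astype(np.uint8)
        c = centroid_of(mask)
        assert c.x == pytest.approx(n / 3, abs=1.0)
        assert c.y == pytest.approx(n / 3, abs=1.0)

    def test_moments_match_pixel_sums(self):
        mask = disc_mask(9)
        m = moments(mask)
        ys, xs = np.nonzero(mask)
        assert m.m00 == len(xs)
        assert m.m10 == xs.sum()
        assert m.m01 == ys.sum()

    def test_empty_region_rejected(self):
        with pytest.raises(NoLumenFound):
            centroid_of(np.zeros((4, 4)))

    def test_centroid_strictly_inside_convex_phantom(self, small_battery):
        for _, img, _ in small_battery[:6]:
            mask = (img[..., 0] > 127).astype(np.uint8)
            c = centroid_of(mask)
            assert mask[int(round(c.y)), int(round(c.x))] == 1


class TestPolarQuadrants:
    def test_axis_point(self):
        pts = to_polar_quadrants(np.array([[15.0, 10.0]]), Centroid(10.0, 10.0))
        assert pts[0].quadrant == "+x"
        assert pts[0].rho == 5.0

    def test_3_4_5_triangle(self):
        pts = to_polar_quadrants(np.array([[13.0, 6.0]]), Centroid(10.0, 10.0))
        assert pts[0].rho == pytest.approx(5.0)
        assert pts[0].quadrant == "Q4"  # dx > 0, dy < 0 (y points down)

    def test_centroid_coincident_point_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="coincident"):
            pts = to_polar_quadrants(
                np.array([[10.0, 10.0], [15.0, 10.0], [5.0, 10.0]]), Centroid(10.2, 10.2)
            )
        assert len(pts) == 2

    def test_circle_quadrant_counts_balanced(self):
        contour = extract_contour(disc_mask(40))
        c = centroid_of(disc_mask(40))
        pts = to_polar_quadrants(contour, c)
        counts = {q: sum(p.quadrant == q for p in pts) for q in ("Q1", "Q2", "Q3", "Q4")}
        mean = np.mean(list(counts.values()))
        for q, n in counts.items():
            assert abs(n - mean) <= 0.05 * len(pts)

    def test_rho_equals_euclidean_norm(self):
        contour = extract_contour(disc_mask(20))
        c = centroid_of(disc_mask(20))
        for p, (x, y) in zip(to_polar_quadrants(contour, c, zero_tol=0.0), contour):
            assert p.rho == pytest.approx(math.hypot(x - c.x, y - c.y))


class TestFindMinDiameter:
    def _polar(self, mask):
        contour = extract_contour(mask)
        return to_polar_quadrants(contour, centroid_of(mask)), contour, centroid_of(mask)

    def test_circle_radius_50(self):
        pts, _, _ = self._polar(disc_mask(50))
        assert 98 <= find_min_diameter(pts).px <= 102

    def test_axis_aligned_ellipse(self):
        img, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=60, b=30))
        mask = (img[..., 0] > 127).astype(np.uint8)
        pts, _, _ = self._polar(mask)
        assert 58 <= find_min_diameter(pts).px <= 62

    def test_rotation_changes_little(self):
        results = []
        for rot in (0.0, 30.0):
            img, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=60, b=30, rotation=rot))
            pts, _, _ = self._polar((img[..., 0] > 127).astype(np.uint8))
            results.append(find_min_diameter(pts).px)
        assert abs(results[0] - results[1]) <= 2.0

    def test_against_brute_force_chord_oracle(self):
        for radius in (20, 35, 50):
            mask = disc_mask(radius)
            pts, contour, c = self._polar(mask)
            alg = find_min_diameter(pts).px
            oracle = min_centroid_chord(contour, c)
            assert oracle <= alg <= oracle + 3.0

    def test_exact_slope_match_equals_euclidean_distance(self):
        # two exactly collinear points through the origin: length rho1+rho2
        # must equal the Euclidean distance between them
        p = PolarContourPoint("Q1", math.hypot(3, 4), math.atan2(4, 3))
        q = PolarContourPoint("Q3", math.hypot(6, 8), math.atan2(-8, -6))
        r = find_min_diameter([p, q])
        dist = math.hypot(3 - (-6), 4 - (-8))
        assert r.px == pytest.approx(dist, abs=1e-9)

    def test_no_candidate_raises(self):
        pts = [
            PolarContourPoint("Q1", 5.0, math.atan(0.2)),
            PolarContourPoint("Q3", 5.0, math.atan(3.0) - math.pi),
        ]
        with pytest.raises(NoDiameterFound):
            find_min_diameter(pts, DiameterSearchParams(slope_abs_tol=1e-6))

    def test_monotone_in_minor_axis(self):
        """Shrinking the minor axis never increases the measured diameter."""
        prev = math.inf
        for b in (45, 35, 25, 18):
            img, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=50, b=b, rotation=25))
            pts, _, _ = self._polar((img[..., 0] > 127).astype(np.uint8))
            d = find_min_diameter(pts).px
            assert d <= prev + 1e-9
            prev = d


class TestCalibration:
    def test_published_scale(self):
        cal = calibrate(10, 379)
        assert round(cal.mm_per_px, 3) == 0.026

    @pytest.mark.parametrize("mm, px, expected", [(1, 1, 1.0), (10, 758, 10 / 758)])
    def test_simple_scales(self, mm, px, expected):
        assert calibrate(mm, px).mm_per_px == pytest.approx(expected)

    @pytest.mark.parametrize("mm, px", [(0, 10), (10, 0), (-1, 1)])
    def test_nonpositive_rejected(self, mm, px):
        with pytest.raises(ValueError):
            calibrate(mm, px)


class TestMeasure:
    def test_disc_in_millimetres(self):
        img, _ = generate_cross_section(PhantomSpec(shape="disc", a=50, b=50, width=151, height=151))
        m = measure(img, ScaleCalibration(0.026))
        assert m.diameter_mm == pytest.approx(2.6, abs=0.06)  # 2 px tolerance

    def test_identity_calibration(self):
        img, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=45, b=30))
        m = measure(img, ScaleCalibration(1.0))
        assert m.diameter_mm == m.diameter_px

    def test_scale_equivariance(self):
        """Doubling the image scale and halving mm/px leaves mm unchanged within 2 %."""
        img1, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=30, b=20, rotation=40, width=151, height=151))
        img2, _ = generate_cross_section(PhantomSpec(shape="ellipse", a=60, b=40, rotation=40, width=301, height=301))
        m1 = measure(img1, ScaleCalibration(0.05))
        m2 = measure(img2, ScaleCalibration(0.025))
        assert m2.diameter_mm == pytest.approx(m1.diameter_mm, rel=0.02)

    def test_measure_mask_warnings_collected(self):
        mask = disc_mask(12)
        # force a centroid-coincident point by adding a spur through the centre
        m = measure_mask(mask, ScaleCalibration(1.0))
        assert isinstance(m.warnings, list)
        assert m.n_candidates > 0
        assert m.n_boundary_points >= 3

    def test_unsegmentable_image_propagates(self):
        with pytest.raises(NoLumenFound):
            measure(np.full((50, 50, 3), 255, dtype=np.uint8), ScaleCalibration(1.0))
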