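"""Boundary extraction, ellipse-template landmarks and triangle features."""

import math
from itertools import combinations

import numpy as np
import pytest
from skimage.draw import ellipse_perimeter

import nucmorph as nm

from conftest import random_blob


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestExtractBoundary:
    def test_small_square_boundary(self):
        m = np.zeros((7, 7), dtype=bool)
        m[2:5, 2:5] = True
        b = nm.extract_boundary(m)
        assert len(b) == 8  # every square pixel except the center

    def test_disk_boundary_length_near_circumference(self):
        m = _disk((64, 64), (31, 31), 15)
        b = nm.extract_boundary(m)
        circ = 2 * math.pi * 15
        assert 0.8 * circ <= len(b) <= 1.3 * circ

    def test_holes_are_filled(self):
        m = _disk((64, 64), (31, 31), 15) & ~_disk((64, 64), (31, 31), 5)
        b = nm.extract_boundary(m)
        rad = np.hypot(b[:, 0] - 31, b[:, 1] - 31)
        assert rad.min() > 10  # no inner-ring boundary pixels

    def test_multiple_components_raise(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:5, 2:5] = True
        m[10:13, 10:13] = True
        with pytest.raises(ValueError, match="components"):
            nm.extract_boundary(m)

    def test_canny_backend_close_to_gradient(self, rng):
        m = random_blob(rng)
        bg = nm.extract_boundary(m, method="gradient")
        bc = nm.extract_boundary(m, method="canny")
        # both trace the same contour: mean nearest distance below 2 px
        d = np.min(np.hypot(bg[:, None, 0] - bc[None, :, 0],
                            bg[:, None, 1] - bc[None, :, 1]), axis=1)
        assert d.mean() < 2.0


class TestEllipseTemplate:
    def test_template_points_follow_parametric_form(self, rng):
        m = random_blob(rng, aspect=(1.5, 1.8), eps=(0.0, 0.0))
        posed, _ = nm.align(m, scale=False)
        t = nm.ellipse_template(posed, k=12)
        # at theta=0: (a, 0); pi/2: (0, b); pi/6: (a*cos, b*sin) -- y up
        for j, ang in enumerate(t.angles):
            dx = t.points[j, 1] - t.center[1]
            dy = -(t.points[j, 0] - t.center[0])
            assert dx == pytest.approx(t.a * math.cos(ang), abs=1e-9)
            assert dy == pytest.approx(t.b * math.sin(ang), abs=1e-9)

    def test_interval_is_pi_over_6_for_k12(self, rng):
        m = random_blob(rng)
        posed, _ = nm.align(m, scale=False)
        t = nm.ellipse_template(posed, k=12)
        assert np.allclose(np.diff(t.angles), math.pi / 6)

    def test_semi_axes_match_known_ellipse(self):
        m = np.zeros((101, 101), dtype=bool)
        rr, cc = np.mgrid[0:101, 0:101]
        m[((cc - 50) / 30) ** 2 + ((rr - 50) / 14) ** 2 <= 1] = True
        t = nm.ellipse_template(m)
        assert t.a == pytest.approx(30, rel=0.05)
        assert t.b == pytest.approx(14, rel=0.05)

    def test_degenerate_mask_raises(self):
        m = np.zeros((50, 50), dtype=bool)
        m[25, 10:40] = True  # one-pixel line: minor axis collapses
        with pytest.raises(ValueError, match="degenerate"):
            nm.ellipse_template(m)


class TestBoundaryFeaturePoints:
    def test_ellipse_boundary_matches_template(self):
        m = np.zeros((101, 101), dtype=bool)
        rr, cc = np.mgrid[0:101, 0:101]
        m[((cc - 50) / 30) ** 2 + ((rr - 50) / 15) ** 2 <= 1] = True
        t = nm.ellipse_template(m)
        b = nm.extract_boundary(m)
        lm = nm.boundary_feature_points(b, t)
        d = np.hypot(*(lm.points - t.points).T)
        assert d.max() <= 2.0  # template radius vs moment-based semi-axes

    def test_single_pixel_boundary_degenerates(self):
        t = nm.EllipseTemplate(a=5, b=3, center=(10, 10),
                               angles=np.arange(12) * math.pi / 6,
                               points=np.random.default_rng(0).uniform(0, 20, (12, 2)))
        lm = nm.boundary_feature_points(np.array([[7, 9]]), t)
        assert (lm.points == [7, 9]).all()

    def test_matches_exhaustive_nearest_neighbour(self, rng):
        """Exact pixel agreement with brute-force search + tie rule."""
        for _ in range(5):
            m = random_blob(rng)
            posed, _ = nm.align(m, scale=False)
            t = nm.ellipse_template(posed)
            b = nm.extract_boundary(posed)
            lm = nm.boundary_feature_points(b, t)
            blist = sorted(map(tuple, b.astype(int)))
            for j in range(12):
                best = min(blist, key=lambda p: (
                    (p[0] - t.points[j, 0]) ** 2 +
                    (p[1] - t.points[j, 1]) ** 2, p))
                assert tuple(lm.points[j].astype(int)) == best


class TestTriangleFeatures:
    @pytest.mark.parametrize("k,expected", [(5, 10), (6, 20), (7, 35),
                                            (8, 56), (9, 84), (10, 120),
                                            (11, 165), (12, 220)])
    def test_triangle_count_is_k_choose_3(self, k, expected, rng):
        pts = rng.uniform(0, 100, (k, 2))
        f = nm.triangle_features(pts, mode="paper")
        assert len(f.values) == expected

    def test_full_mode_doubles_dimensions(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        assert len(nm.triangle_features(pts, mode="full").values) == 440

    def test_equilateral_triangle_cosines(self):
        pts = np.array([[0, 0], [0, 4], [4 * math.sin(math.pi / 3), 2]])
        f = nm.triangle_features(pts, mode="full")
        assert np.allclose(f.values, 0.5, atol=1e-9)

    def test_3_4_5_right_triangle(self):
        # vertices i=(0,0), j=(4,0), k=(4,3) as (x, y) pairs
        pts = np.array([[0.0, 0.0], [0.0, 4.0], [3.0, 4.0]])  # (row, col)
        f = nm.triangle_features(pts, mode="full")
        assert f.values["bf.0.1.2.j"] == pytest.approx(0.0, abs=1e-12)
        assert f.values["bf.0.1.2.k"] == pytest.approx(3 / 5, abs=1e-12)

    def test_angle_sum_and_cosine_range(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        f = nm.triangle_features(pts, mode="full")
        for (i, j, k) in f.triples:
            cj = f.values[f"bf.{i}.{j}.{k}.j"]
            ck = f.values[f"bf.{i}.{j}.{k}.k"]
            # third angle from the other two: angles must sum to pi
            ai = math.pi - math.acos(cj) - math.acos(ck)
            assert 0 < ai < math.pi
            assert -1 < cj < 1 and -1 < ck < 1

    def test_agrees_with_dot_product_oracle(self, rng):
        """Law-of-cosines values equal vertex-wise dot products, 100 sets."""
        for _ in range(100):
            pts = rng.uniform(0, 50, (6, 2))
            f = nm.triangle_features(pts, mode="full")
            for (i, j, k) in f.triples:
                u = pts[i] - pts[j]
                v = pts[k] - pts[j]
                cj = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                u2 = pts[i] - pts[k]
                v2 = pts[j] - pts[k]
                ck = u2 @ v2 / (np.linalg.norm(u2) * np.linalg.norm(v2))
                assert f.values[f"bf.{i}.{j}.{k}.j"] == pytest.approx(cj, abs=1e-9)
                assert f.values[f"bf.{i}.{j}.{k}.k"] == pytest.approx(ck, abs=1e-9)

    def test_scale_invariance_on_continuous_landmarks(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        f1 = nm.triangle_features(pts).values
        f2 = nm.triangle_features(pts * 3.7).values
        assert np.abs(f1 - f2).max() < 1e-6

    def test_collinear_triple_flagged_degenerate(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [5.0, 5.0]])
        f = nm.triangle_features(pts)
        assert f.n_degenerate >= 1

    def test_too_few_landmarks_raise(self):
        with pytest.raises(ValueError):
            nm.triangle_features(np.zeros((2, 2)))
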