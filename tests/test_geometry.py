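"""Rotated-rectangle arithmetic against independent geometric oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from henstrack.geometry import (RotatedRect, SearchConfig, angle_candidates,
                                corners, min_outer_rect, overlap_rate,
                                rotate_point, search_boxes, search_centers)


def rotmat_oracle(p, center, deg):
    """Independent rotation: explicit 2x2 matrix multiply about center."""
    th = math.radians(deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return R @ (np.asarray(p, float) - center) + center


def raster_iou(a, b, res=0.01):
    """Independent IoU: pixel-center rasterization of both rectangles."""
    cs = np.vstack([corners(a), corners(b)])
    x0, y0 = cs.min(axis=0) - res
    x1, y1 = cs.max(axis=0) + res
    X, Y = np.meshgrid(np.arange(x0 + res / 2, x1, res),
                       np.arange(y0 + res / 2, y1, res))

    def inside(r):
        th = math.radians(r.a)
        c, s = math.cos(th), math.sin(th)
        u = (X - r.cx) * c + (Y - r.cy) * s
        v = -(X - r.cx) * s + (Y - r.cy) * c
        return (np.abs(u) <= r.w / 2) & (np.abs(v) <= r.h / 2)

    A, B = inside(a), inside(b)
    union = (A | B).sum()
    return (A & B).sum() / union if union else 0.0


def sweep_min_rect_area(pts, step=0.1):
    """Independent minimum-rectangle area: brute-force angle sweep."""
    pts = np.asarray(pts, float)
    best = np.inf
    for deg in np.arange(0.0, 90.0, step):
        th = math.radians(deg)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        q = pts @ R.T
        ext = q.max(axis=0) - q.min(axis=0)
        best = min(best, ext[0] * ext[1])
    return best


class TestRotatedRect:
    def test_angle_normalized_into_half_open_interval(self):
        for a in (-270.0, -90.0, 0.0, 89.9, 90.0, 104.0, 360.0):
            r = RotatedRect(0, 0, 4, 2, a)
            assert -90.0 <= r.a < 90.0

    def test_equivalent_angles_give_identical_corners(self):
        r1 = RotatedRect(3, 4, 5, 2, 104.0)
        r2 = RotatedRect(3, 4, 5, 2, -76.0)
        np.testing.assert_allclose(corners(r1), corners(r2), atol=1e-9)

    @pytest.mark.parametrize("w,h", [(0, 2), (-1, 2), (3, 0)])
    def test_rejects_nonpositive_size(self, w, h):
        with pytest.raises(ValueError):
            RotatedRect(0, 0, w, h)

    def test_corner_polygon_area_equals_w_times_h(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = RotatedRect(*rng.uniform(-5, 5, 2), *rng.uniform(0.5, 9, 2),
                            rng.uniform(-180, 180))
            xy = corners(r)
            shoelace = 0.5 * abs(np.dot(xy[:, 0], np.roll(xy[:, 1], -1))
                                 - np.dot(xy[:, 1], np.roll(xy[:, 0], -1)))
            assert shoelace == pytest.approx(r.w * r.h, rel=1e-6)


class TestRotatePoint:
    def test_center_is_fixed(self):
        assert rotate_point((3, 4), (3, 4), 37.0, 1, 4, 3.0) == (3, 4)

    def test_zero_steps_zero_angle_is_identity(self):
        assert rotate_point((2, 5), (0, 0), 0.0, 2, 0, 3.0) == (2, 5)

    def test_quarter_turn_example(self):
        x, y = rotate_point((1, 0), (0, 0), 0.0, 2, 1, 90.0)
        assert (x, y) == pytest.approx((0.0, 1.0), abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50),
           st.floats(-50, 50), st.floats(-180, 180),
           st.integers(1, 2), st.integers(0, 8), st.floats(0.1, 30))
    def test_matches_rotation_matrix_oracle(self, px, py, cx, cy, a0, i, n, k):
        got = rotate_point((px, py), (cx, cy), a0, i, n, k)
        want = rotmat_oracle((px, py), np.array([cx, cy]),
                             a0 + (-1.0) ** i * n * k)
        np.testing.assert_allclose(got, want, atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-20, 20), st.floats(-20, 20), st.integers(0, 6),
           st.floats(0.5, 20))
    def test_isometry_and_inverse(self, px, py, n, k):
        center = (1.5, -2.0)
        fwd = rotate_point((px, py), center, 10.0, 1, n, k)
        d0 = math.hypot(px - center[0], py - center[1])
        d1 = math.hypot(fwd[0] - center[0], fwd[1] - center[1])
        assert d1 == pytest.approx(d0, abs=1e-9)
        back = rotate_point(fwd, center, -10.0, 2, n, k)
        # i=1 then i=2 with equal total angle returns to the start
        np.testing.assert_allclose(back, (px, py), atol=1e-9)


class TestAngleCandidates:
    def test_zero_steps_returns_only_the_box(self):
        box = RotatedRect(10, 10, 6, 4, 12.0)
        assert angle_candidates(box, SearchConfig(h_steps=0)) == [box]

    def test_default_count_and_span(self):
        box = RotatedRect(10, 10, 6, 4, 0.0)
        cands = angle_candidates(box, SearchConfig())
        assert len(cands) == 11
        assert [c.a for c in cands] == list(np.arange(-15.0, 16.0, 3.0))
        assert cands[5] == box

    def test_wraparound_candidate_has_identical_polygon(self):
        box = RotatedRect(10, 10, 6, 4, 89.0)
        cand = angle_candidates(box, SearchConfig())[-1]  # j=+5 -> 104 deg
        raw = RotatedRect.__new__(RotatedRect)
        np.testing.assert_allclose(
            corners(cand),
            corners(RotatedRect(10, 10, 6, 4, 104.0)), atol=1e-9)
        assert -90.0 <= cand.a < 90.0


class TestSearchCenters:
    def test_degenerate_grid_is_single_start_offset(self):
        # with M=N=1 the sole center sits at the search-box start position
        box = RotatedRect(50, 60, 100, 50, 0.0)
        (cx, cy), = search_centers(box, SearchConfig(m_cols=1, n_rows=1))
        assert (cx, cy) == pytest.approx((50 - 10.0, 60 - 5.0))

    def test_axis_aligned_first_offset_hand_value(self):
        box = RotatedRect(0, 0, 100, 50, 0.0)
        centers = search_centers(box, SearchConfig())
        assert centers[0] == pytest.approx((-0.1 * 100, -0.1 * 50))

    def test_grid_size_and_shared_geometry(self):
        box = RotatedRect(5, 5, 10, 8, 33.0)
        cfg = SearchConfig()
        boxes = search_boxes(box, cfg)
        assert len(boxes) == cfg.m_cols * cfg.n_rows == 25
        assert all((b.w, b.h, b.a) == (box.w, box.h, box.a) for b in boxes)

    def test_rotating_box_rotates_offset_grid(self):
        cfg = SearchConfig()
        base = RotatedRect(20, 30, 12, 8, 0.0)
        rot = base.with_angle(90.0)  # normalizes to -90, same rectangle
        grid0 = np.asarray(search_centers(base, cfg))
        grid_rot = np.asarray(search_centers(rot, cfg))
        expected = np.asarray([
            rotmat_oracle(p, np.array([20.0, 30.0]), rot.a) for p in grid0
        ])
        np.testing.assert_allclose(grid_rot, expected, atol=1e-9)

    def test_symmetric_grid_has_zero_mean_and_zero_offset(self):
        box = RotatedRect(0, 0, 40, 20, 0.0)
        centers = np.asarray(search_centers(box, SearchConfig(symmetric_grid=True)))
        np.testing.assert_allclose(centers.mean(axis=0), [0, 0], atol=1e-12)
        assert any(np.hypot(*c) < 1e-12 for c in centers)

    def test_evaluation_budget_counts(self):
        cfg = SearchConfig()
        assert cfg.evaluations_per_alternation == 36
        assert cfg.naive_evaluations_per_alternation == 275


class TestCorners:
    def test_unit_square_axis_aligned(self):
        got = {tuple(p) for p in np.round(corners(RotatedRect(0, 0, 2, 2, 0)), 9)}
        assert got == {(-1, -1), (1, -1), (1, 1), (-1, 1)}

    def test_square_is_invariant_under_quarter_turn(self):
        a0 = {tuple(p) for p in np.round(corners(RotatedRect(0, 0, 2, 2, 0)), 6)}
        a90 = {tuple(p) for p in np.round(corners(RotatedRect(0, 0, 2, 2, 90)), 6)}
        assert a0 == a90


class TestOverlapRate:
    def test_identity_and_disjoint(self):
        a = RotatedRect(0, 0, 4, 4, 17.0)
        assert overlap_rate(a, a) == 1.0
        assert overlap_rate(a, RotatedRect(100, 100, 4, 4, 0)) == 0.0

    def test_hand_value_axis_aligned(self):
        a = RotatedRect(0, 0, 4, 4, 0)
        b = RotatedRect(2, 0, 4, 4, 0)
        assert overlap_rate(a, b) == pytest.approx(1 / 3, abs=1e-12)

    def test_symmetric_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = RotatedRect(*rng.uniform(-3, 3, 2), *rng.uniform(1, 6, 2),
                            rng.uniform(-90, 90))
            b = RotatedRect(*rng.uniform(-3, 3, 2), *rng.uniform(1, 6, 2),
                            rng.uniform(-90, 90))
            assert overlap_rate(a, b) == pytest.approx(overlap_rate(b, a), abs=1e-12)
            # joint rigid motion
            dx, dy, rot = rng.uniform(-10, 10, 3)

            def moved(r):
                c = rotmat_oracle((r.cx, r.cy), np.zeros(2), rot) + [dx, dy]
                return RotatedRect(c[0], c[1], r.w, r.h, r.a + rot)

            assert overlap_rate(moved(a), moved(b)) == pytest.approx(
                overlap_rate(a, b), abs=1e-6)

    def test_agrees_with_rasterization_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            a = RotatedRect(*rng.uniform(8, 14, 2), *rng.uniform(3, 10, 2),
                            rng.uniform(-90, 90))
            b = RotatedRect(*rng.uniform(8, 14, 2), *rng.uniform(3, 10, 2),
                            rng.uniform(-90, 90))
            assert overlap_rate(a, b) == pytest.approx(raster_iou(a, b), abs=1e-3)


class TestMinOuterRect:
    def test_recovers_axis_aligned_rectangle(self):
        pts = [(1, 2), (9, 2), (9, 7), (1, 7)]
        r = min_outer_rect(pts)
        assert (r.cx, r.cy) == pytest.approx((5, 4.5))
        assert sorted([r.w, r.h]) == pytest.approx([5, 8])
        assert r.a == pytest.approx(0.0, abs=1e-9)

    def test_recovers_rotated_rectangle(self):
        base = np.array([(0, 0), (8, 0), (8, 4), (0, 4)], float)
        rot = np.array([rotmat_oracle(p, np.zeros(2), 30.0) for p in base])
        r = min_outer_rect(rot)
        assert sorted([r.w, r.h]) == pytest.approx([4, 8], abs=1e-6)
        assert abs(r.a % 90) == pytest.approx(30.0, abs=1e-6) or \
            abs(r.a % 90) == pytest.approx(60.0, abs=1e-6)
        assert r.area == pytest.approx(sweep_min_rect_area(rot), rel=1e-3)

    def test_triangle_area_matches_sweep_oracle(self):
        tri = [(0, 0), (1, 0), (0, 1)]
        r = min_outer_rect(tri)
        assert r.area == pytest.approx(sweep_min_rect_area(tri), rel=1e-3)

    def test_all_points_enclosed_and_area_below_aabb(self):
        rng = np.random.default_rng(9)
        from shapely.geometry import Point
        for _ in range(20):
            pts = rng.uniform(0, 20, size=(rng.integers(3, 12), 2))
            try:
                r = min_outer_rect(pts)
            except ValueError:
                continue  # collinear draw
            poly = r.polygon().buffer(1e-6)
            assert all(poly.contains(Point(*p)) for p in pts)
            ext = pts.max(axis=0) - pts.min(axis=0)
            assert r.area <= ext[0] * ext[1] + 1e-6

    def test_rejects_collinear_points(self):
        with pytest.raises(ValueError):
            min_outer_rect([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            min_outer_rect([(0, 0), (1, 1)])
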