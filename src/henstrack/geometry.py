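"""Rotated-rectangle arithmetic for the tracker state.

The tracker represents its target as an oriented rectangle
``T{w, h, a, c}`` — width, height, angle to the image x-axis and center —
in continuous image coordinates (origin top-left, x right, y down).
This module provides construction and normalization of that state, the
rotation and displacement candidate generators used by the search loop,
polygon conversion, the overlap rate (rotated IoU) used both as the
regression target and as the evaluation metric, and the minimum-area
outer rectangle of a hand-marked contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "RotatedRect",
    "SearchConfig",
    "rotate_point",
    "angle_candidates",
    "search_centers",
    "search_boxes",
    "corners",
    "overlap_rate",
    "min_outer_rect",
]


def _normalize_angle(a: float) -> float:
    """Reduce an angle in degrees to [-90, 90).

    A rectangle is invariant under a -> a + 180, so this loses nothing;
    representations at +/-90 are equivalent to a w/h swap at 0.
    """
    return float((a + 90.0) % 180.0 - 90.0)


@dataclass(frozen=True)
class RotatedRect:
    """Oriented rectangle: center ``(cx, cy)``, size ``(w, h)``, angle ``a``.

    ``a`` is the angle in degrees between the rectangle's width axis and
    the image x-axis, stored normalized to ``[-90, 90)``. ``w`` and ``h``
    must be strictly positive.
    """

    cx: float
    cy: float
    w: float
    h: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.cx, self.cy, self.w, self.h, self.a))):
            raise ValueError("rotated rectangle parameters must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"width and height must be positive, got {self.w}x{self.h}")
        object.__setattr__(self, "a", _normalize_angle(self.a))

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    @property
    def diagonal(self) -> float:
        return math.hypot(self.w, self.h)

    @property
    def area(self) -> float:
        return self.w * self.h

    def with_center(self, cx: float, cy: float) -> "RotatedRect":
        return replace(self, cx=cx, cy=cy)

    def with_angle(self, a: float) -> "RotatedRect":
        return replace(self, a=a)

    def polygon(self) -> Polygon:
        return Polygon(corners(self))


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the alternating angle/displacement search.

    ``h_steps`` rotations of ``k_deg`` degrees each are tried clockwise and
    counterclockwise (2*h_steps + 1 angle candidates); the best-angle box is
    expanded ``m_expand`` times to define the shift search area, scanned by
    an ``m_cols`` x ``n_rows`` grid of same-size boxes. Angle and shift steps
    alternate until two successive quasi-tracking areas coincide (within the
    given tolerances) or ``max_alternations`` is reached.
    """

    h_steps: int = 5
    k_deg: float = 3.0
    m_expand: float = 1.2
    m_cols: int = 5
    n_rows: int = 5
    max_alternations: int = 10
    coincide_tol_px: float = 0.5
    coincide_tol_deg: float = 0.5
    symmetric_grid: bool = False

    def __post_init__(self) -> None:
        if self.h_steps < 0:
            raise ValueError("h_steps must be >= 0")
        if self.k_deg <= 0:
            raise ValueError("k_deg must be > 0")
        if self.m_expand <= 1:
            raise ValueError("m_expand must be > 1")
        if self.m_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must be at least 1x1")
        if self.max_alternations < 1:
            raise ValueError("max_alternations must be >= 1")

    @property
    def n_angle_candidates(self) -> int:
        return 2 * self.h_steps + 1

    @property
    def n_shift_candidates(self) -> int:
        return self.m_cols * self.n_rows

    @property
    def evaluations_per_alternation(self) -> int:
        """Region evaluations per alternation: M*N + 2h + 1."""
        return self.n_shift_candidates + self.n_angle_candidates

    @property
    def naive_evaluations_per_alternation(self) -> int:
        """Cost of the joint angle x shift search the alternation avoids."""
        return self.n_shift_candidates * self.n_angle_candidates


def rotate_point(
    p: Sequence[float],
    center: Sequence[float],
    a0: float,
    i: int,
    steps: int,
    k: float,
) -> tuple[float, float]:
    """Rotate point ``p`` about ``center`` by ``a0 + (-1)^i * steps * k`` degrees.

    ``i = 1`` selects the clockwise search direction and ``i = 2`` the
    counterclockwise one; ``steps`` rotations of ``k`` degrees each are
    applied on top of the base angle ``a0``.
    """
    theta = math.radians(a0 + (-1.0) ** i * steps * k)
    x0, y0 = float(center[0]), float(center[1])
    dx, dy = float(p[0]) - x0, float(p[1]) - y0
    c, s = math.cos(theta), math.sin(theta)
    return (dx * c - dy * s + x0, dx * s + dy * c + y0)


def angle_candidates(box: RotatedRect, cfg: SearchConfig) -> list[RotatedRect]:
    """The 2*h_steps + 1 rotation candidates around ``box``, ascending offset.

    All candidates share the center and size of ``box``; angles are
    ``box.a + j*k_deg`` for j = -h_steps ... +h_steps (the original box is
    the j = 0 entry).
    """
    return [
        box.with_angle(box.a + j * cfg.k_deg)
        for j in range(-cfg.h_steps, cfg.h_steps + 1)
    ]


def _grid_offsets(w: float, h: float, cfg: SearchConfig) -> list[tuple[float, float]]:
    """Axis-local displacement offsets of the M x N search grid (row-major)."""
    e = cfg.m_expand - 1.0
    if cfg.symmetric_grid:
        def axis(n: int, extent: float) -> list[float]:
            if n == 1:
                return [0.0]
            return [e * extent * (i / (n - 1) - 0.5) for i in range(n)]
        xs = axis(cfg.m_cols, w)
        ys = axis(cfg.n_rows, h)
    else:
        xs = [-e * 0.5 * w + e / cfg.m_cols * w * i for i in range(cfg.m_cols)]
        ys = [-e * 0.5 * h + e / cfg.n_rows * h * j for j in range(cfg.n_rows)]
    return [(dx, dy) for dy in ys for dx in xs]


def search_centers(best: RotatedRect, cfg: SearchConfig) -> list[tuple[float, float]]:
    """Centers of the M x N displacement candidates around ``best``.

    The grid spans the search area obtained by expanding ``best`` by
    ``m_expand``; local offsets along the box's own width/height axes are
    rotated by the box angle into image coordinates. Row-major order
    (rows j along the height, columns i along the width).
    """
    theta = math.radians(best.a)
    c, s = math.cos(theta), math.sin(theta)
    out = []
    for dx, dy in _grid_offsets(best.w, best.h, cfg):
        out.append((dx * c - dy * s + best.cx, dx * s + dy * c + best.cy))
    return out


def search_boxes(best: RotatedRect, cfg: SearchConfig) -> list[RotatedRect]:
    """The displacement candidates as boxes sharing w, h, a with ``best``."""
    return [best.with_center(x, y) for x, y in search_centers(best, cfg)]


def corners(box: RotatedRect) -> np.ndarray:
    """The 4 vertices of the oriented rectangle, consistent winding, (4, 2)."""
    theta = math.radians(box.a)
    c, s = math.cos(theta), math.sin(theta)
    hw, hh = box.w / 2.0, box.h / 2.0
    local = np.array([(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)])
    rot = np.array([(c, -s), (s, c)])
    return local @ rot.T + np.array([box.cx, box.cy])


def overlap_rate(rt: RotatedRect, rl: RotatedRect) -> float:
    """Intersection-over-union of two oriented rectangles (exact clipping).

    Symmetric, in [0, 1]; 0 exactly when the interiors are disjoint and 1
    when the rectangles coincide.
    """
    if rt == rl:
        return 1.0
    pt, pl = rt.polygon(), rl.polygon()
    inter = pt.intersection(pl).area
    if inter <= 0.0:
        return 0.0
    union = pt.area + pl.area - inter
    return float(inter / union)


def min_outer_rect(contour: Iterable[Sequence[float]]) -> RotatedRect:
    """Minimum-area enclosing oriented rectangle of a point contour.

    This is the rotation method used at initialization: the rectangle of
    minimal area (over all orientations) containing the convex hull of the
    marked contour. Raises ``ValueError`` for degenerate (collinear) input.
    """
    pts = np.asarray(list(contour), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must contain at least 3 (x, y) points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 1e-12:
        raise ValueError("degenerate contour: points are collinear")
    rect = hull.minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    e0 = xy[1] - xy[0]
    e1 = xy[2] - xy[1]
    w = float(np.hypot(*e0))
    h = float(np.hypot(*e1))
    a = math.degrees(math.atan2(e0[1], e0[0]))
    cx, cy = xy.mean(axis=0)
    # canonical representation: width edge within [-45, 45] of the x-axis
    a = _normalize_angle(a)
    if abs(a) > 45.0:
        w, h = h, w
        a = _normalize_angle(a + 90.0)
    return RotatedRect(float(cx), float(cy), w, h, a)
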