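"""Seeded synthetic frame sequences with ground-truth rotated boxes.

Real pen footage of laying hens is proprietary, so every scenario the
tracker is evaluated on is emulated: a textured ellipse (the "hen") moves
over a cluttered static background, optionally accompanied by similar
distractor ellipses that cross and partially occlude it. The four
scenario presets mirror the evaluation taxonomy of hen tracking studies:
change of direction, two-hen mutual occlusion (one crossing distractor),
preening (in-place angle and axis-ratio jitter), and multi-hen mutual
occlusion (several crossing distractors); a plain linear walk is provided
as the easy baseline.

Textures are band-limited random noise rendered in each ellipse's local
frame, so they translate and rotate rigidly with the body and carry the
orientation information the HOG descriptor needs. The ground truth of
frame i is the minimum outer rectangle of the target ellipse, i.e. the
axis-aligned 2A x 2B rectangle in the ellipse's own frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import RotatedRect

__all__ = ["EllipseSpec", "SceneConfig", "generate", "preset_suite", "PRESETS"]

SCENARIOS = ("linear", "direction_change", "crossing_occlusion",
             "multi_occlusion", "preen_jitter")


@dataclass(frozen=True)
class EllipseSpec:
    """A textured ellipse: semi-axes in px, base angle in degrees, texture seed.

    The default size follows the pen geometry the scenes emulate: an
    overhead camera at ~2.2 m over a ~1.2 x 1.5 m pen maps a laying hen to
    an ellipse on the order of 90 x 60 px, large relative to the fixed
    d1 = sqrt(20) px positive-sampling radius the tracker assumes.
    """

    semi_axes: tuple[float, float] = (44.0, 29.0)
    angle: float = 0.0
    texture_seed: int = 0
    contrast: float = 70.0
    mean_intensity: float = 130.0


@dataclass(frozen=True)
class SceneConfig:
    frame_size: tuple[int, int] = (320, 240)  # (width, height)
    n_frames: int = 50
    target: EllipseSpec = field(default_factory=EllipseSpec)
    distractors: tuple[EllipseSpec, ...] = ()
    trajectory: str = "linear"
    speed: float = 3.0  # px/frame
    turn_frames: tuple[int, ...] = (20, 40)
    turn_angles: tuple[float, ...] = (60.0, -90.0)
    jitter_angle_amp: float = 20.0  # degrees, preening preset
    jitter_axis_amp: float = 0.15  # fractional axis-ratio jitter
    jitter_period: float = 16.0  # frames
    noise_sigma: float = 4.0
    background_seed: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if min(self.target.semi_axes) * 2 < 12:
            raise ValueError("target axes below 12 px break the sampling regime")
        if self.trajectory not in SCENARIOS:
            raise ValueError(f"unknown trajectory preset {self.trajectory!r}")


def _smooth_noise(shape: tuple[int, int], seed: int, sigma: float = 2.0) -> np.ndarray:
    """Band-limited noise field in [-1, 1]."""
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal(shape), sigma)
    field_ /= max(np.abs(field_).max(), 1e-9)
    return field_


def _target_track(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (center, heading angle, semi-axes) of the target."""
    w, h = cfg.frame_size
    n = cfg.n_frames
    centers = np.zeros((n, 2))
    angles = np.zeros(n)
    axes = np.tile(np.asarray(cfg.target.semi_axes, dtype=float), (n, 1))

    if cfg.trajectory == "preen_jitter":
        centers[:] = (w / 2.0, h / 2.0)
        t = np.arange(n)
        angles = cfg.target.angle + cfg.jitter_angle_amp * np.sin(
            2.0 * math.pi * t / cfg.jitter_period)
        ratio = 1.0 + cfg.jitter_axis_amp * np.sin(
            2.0 * math.pi * t / cfg.jitter_period + math.pi / 3.0)
        axes[:, 1] = axes[:, 1] * ratio
        return centers, angles, axes

    if cfg.trajectory == "direction_change":
        # piecewise-constant heading with smooth turns over ~6 frames
        heading = np.full(n, cfg.target.angle, dtype=float)
        for tf, ta in zip(cfg.turn_frames, cfg.turn_angles):
            ramp = np.clip((np.arange(n) - tf) / 6.0, 0.0, 1.0)
            heading = heading + ramp * ta
        angles = heading
    else:
        angles[:] = cfg.target.angle

    # integrate motion along the heading
    margin = max(cfg.target.semi_axes) + 6.0
    if margin > w - margin or margin > h - margin:
        raise ValueError("target cannot fit its trajectory inside the frame")
    pos = np.array([w * 0.25, h * 0.5]) if cfg.trajectory != "linear" else \
        np.array([w * 0.2, h * 0.5])
    for i in range(n):
        centers[i] = pos
        th = math.radians(angles[i])
        pos = pos + cfg.speed * np.array([math.cos(th), math.sin(th)])
        pos = np.clip(pos, margin, [w - margin, h - margin])
    return centers, angles, axes


def _distractor_tracks(cfg: SceneConfig, centers: np.ndarray) -> list[np.ndarray]:
    """Straight-line distractor paths engineered to cross the target."""
    n = cfg.n_frames
    w, h = cfg.frame_size
    tracks = []
    for d_idx, _spec in enumerate(cfg.distractors):
        cross_frame = int(n * (0.45 + 0.12 * d_idx))
        cross_frame = min(cross_frame, n - 5)
        target_at_cross = centers[cross_frame]
        # pass through a point offset from the target center so occlusion
        # stays partial; alternate above/below for multiple distractors
        sign = 1.0 if d_idx % 2 == 0 else -1.0
        offset = np.array([0.0, sign * 0.8 * cfg.target.semi_axes[1]])
        cross_point = target_at_cross + offset
        speed = cfg.speed * 1.6 + 0.4 * d_idx
        direction = np.array([-1.0, 0.0])  # moves right-to-left against target
        t = (np.arange(n) - cross_frame)[:, None]
        track = cross_point[None, :] + direction[None, :] * speed * t
        track[:, 1] = np.clip(track[:, 1], 8.0, h - 8.0)
        tracks.append(track)
    return tracks


def _render_ellipse(canvas: np.ndarray, spec: EllipseSpec, center: np.ndarray,
                    angle: float, axes: np.ndarray, texture: np.ndarray) -> None:
    """Draw one textured ellipse with a soft anti-aliased edge, in place."""
    h, w = canvas.shape
    A, B = float(axes[0]), float(axes[1])
    r = int(math.ceil(max(A, B))) + 2
    x0, x1 = int(center[0]) - r, int(center[0]) + r + 1
    y0, y1 = int(center[1]) - r, int(center[1]) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs, ys = np.meshgrid(np.arange(x0c, x1c), np.arange(y0c, y1c))
    th = math.radians(angle)
    c, s = math.cos(th), math.sin(th)
    dx, dy = xs - center[0], ys - center[1]
    u = dx * c + dy * s
    v = -dx * s + dy * c
    q = np.sqrt((u / A) ** 2 + (v / B) ** 2)
    alpha = np.clip((1.0 - q) * max(A, B) * 0.5, 0.0, 1.0)  # ~2 px soft edge
    if not np.any(alpha > 0):
        return
    # sample the ellipse's own texture field in its local frame
    tex_h, tex_w = texture.shape
    ti = (v / B + 1.0) * 0.5 * (tex_h - 1)
    tj = (u / A + 1.0) * 0.5 * (tex_w - 1)
    tex = map_coordinates(texture, [ti, tj], order=1, mode="nearest")
    value = spec.mean_intensity + spec.contrast * tex
    region = canvas[y0c:y1c, x0c:x1c]
    canvas[y0c:y1c, x0c:x1c] = (1.0 - alpha) * region + alpha * value


def generate(cfg: SceneConfig
             ) -> tuple[list[np.ndarray], list[RotatedRect], list[str]]:
    """Render the scene: (frames, ground-truth boxes, per-frame scenario tags).

    Frames are 8-bit grayscale; truth[i] is the minimum outer rectangle of
    the target ellipse at frame i. Deterministic given ``cfg.seed``.
    """
    w, h = cfg.frame_size
    centers, angles, axes = _target_track(cfg)
    if np.any(centers[:, 0] < -1) or np.any(centers[:, 0] > w + 1) or \
            np.any(centers[:, 1] < -1) or np.any(centers[:, 1] > h + 1):
        raise ValueError("trajectory leaves the frame entirely")
    d_tracks = _distractor_tracks(cfg, centers)

    background = 110.0 + 25.0 * _smooth_noise((h, w), cfg.background_seed, 3.0)
    tgt_tex = _smooth_noise((48, 48), cfg.target.texture_seed + cfg.seed * 1000 + 1, 1.6)
    d_texs = [
        _smooth_noise((48, 48), spec.texture_seed + cfg.seed * 1000 + 101 + i, 1.6)
        for i, spec in enumerate(cfg.distractors)
    ]
    noise_rng = np.random.default_rng(cfg.seed + 77)

    frames, truth, tags = [], [], []
    for i in range(cfg.n_frames):
        canvas = background.copy()
        # distractors first, then the target on top of all but the crossing
        # distractor, which passes in front to produce genuine occlusion
        for k, (spec, track) in enumerate(zip(cfg.distractors, d_tracks)):
            if k % 2 == 1:
                _render_ellipse(canvas, spec, track[i], spec.angle,
                                np.asarray(spec.semi_axes), d_texs[k])
        _render_ellipse(canvas, cfg.target, centers[i], angles[i], axes[i], tgt_tex)
        for k, (spec, track) in enumerate(zip(cfg.distractors, d_tracks)):
            if k % 2 == 0:
                _render_ellipse(canvas, spec, track[i], spec.angle,
                                np.asarray(spec.semi_axes), d_texs[k])
        if cfg.noise_sigma > 0:
            canvas = canvas + noise_rng.normal(0.0, cfg.noise_sigma, canvas.shape)
        frames.append(np.clip(canvas, 0, 255).astype(np.uint8))
        truth.append(RotatedRect(float(centers[i, 0]), float(centers[i, 1]),
                                 2.0 * float(axes[i, 0]), 2.0 * float(axes[i, 1]),
                                 float(angles[i])))
        tags.append(cfg.trajectory)
    return frames, truth, tags


def occlusion_frames(cfg: SceneConfig, min_fraction: float = 0.05) -> list[int]:
    """Frames where some distractor ellipse covers at least ``min_fraction``
    of the target's area (rasterized overlap of the true ellipses)."""
    centers, angles, axes = _target_track(cfg)
    d_tracks = _distractor_tracks(cfg, centers)
    out = []
    w, h = cfg.frame_size
    ys, xs = np.mgrid[0:h, 0:w]
    for i in range(cfg.n_frames):
        th = math.radians(angles[i])
        c, s = math.cos(th), math.sin(th)
        dx, dy = xs - centers[i, 0], ys - centers[i, 1]
        u, v = dx * c + dy * s, -dx * s + dy * c
        tmask = (u / axes[i, 0]) ** 2 + (v / axes[i, 1]) ** 2 <= 1.0
        area = max(tmask.sum(), 1)
        for spec, track in zip(cfg.distractors, d_tracks):
            ddx, ddy = xs - track[i, 0], ys - track[i, 1]
            thd = math.radians(spec.angle)
            cd, sd = math.cos(thd), math.sin(thd)
            ud, vd = ddx * cd + ddy * sd, -ddx * sd + ddy * cd
            dmask = (ud / spec.semi_axes[0]) ** 2 + (vd / spec.semi_axes[1]) ** 2 <= 1.0
            if (tmask & dmask).sum() / area >= min_fraction:
                out.append(i)
                break
    return out


PRESETS = {
    "linear": SceneConfig(trajectory="linear", n_frames=40),
    "direction_change": SceneConfig(trajectory="direction_change", n_frames=50,
                                    turn_frames=(18, 38),
                                    turn_angles=(55.0, -80.0)),
    "crossing_occlusion": SceneConfig(
        trajectory="crossing_occlusion", n_frames=70,
        distractors=(EllipseSpec(texture_seed=5),)),
    "preen_jitter": SceneConfig(trajectory="preen_jitter", n_frames=40),
    "multi_occlusion": SceneConfig(
        trajectory="multi_occlusion", n_frames=70,
        distractors=(EllipseSpec(texture_seed=5),
                     EllipseSpec(semi_axes=(40.0, 26.0), texture_seed=9),
                     EllipseSpec(semi_axes=(48.0, 31.0), texture_seed=13))),
}

# scenario presets mirroring the evaluation taxonomy (order matters for reports)
SUITE_ORDER = ("direction_change", "crossing_occlusion", "preen_jitter",
               "multi_occlusion")


def preset_suite(seed: int = 0) -> list[SceneConfig]:
    """One configuration per evaluation scenario, re-seeded from ``seed``."""
    return [replace(PRESETS[name], seed=seed) for name in SUITE_ORDER]
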