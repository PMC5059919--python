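"""The per-frame tracking loop.

Each frame starts from the previous frame's box and alternates an angle
search (2h+1 rotation candidates about the current center) with a
displacement search (an MxN grid of same-size boxes spanning the
m-expanded search area), keeping the top-scoring candidate of each step,
until two successive quasi-tracking areas coincide or the alternation
limit is reached. Separating the angle and displacement searches costs
M*N + 2h + 1 region evaluations per alternation instead of the
(M*N)*(2h+1) a joint search would need.

After localization, the appearance-change measure (one minus the best
cosine similarity of the current descriptor to the accepted history)
gates the online update: only results that still resemble a previously
accepted appearance (change below the threshold, 0.05 by default) trigger
re-sampling and re-training — a conservative rule that refuses to learn
from occluded or drifted results.

The box size is fixed for the whole track; only center and angle move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import hsvm_models, sampling
from .geometry import (RotatedRect, SearchConfig, angle_candidates,
                       min_outer_rect, search_boxes)
from .hog_features import HogConfig, appearance_change, extract_patch, hog, hog_batch, extract_patches
from .hsvm_models import FusionWeights, HsvmModel, KernelConfig, best_candidate, score
from .sampling import LabeledSample, SamplePools, SampleRole, thresholds_for

__all__ = ["TrackerConfig", "FrameStats", "TrackerState", "initialize",
           "angle_step", "shift_step", "track_frame", "maybe_update", "run"]


@dataclass(frozen=True)
class TrackerConfig:
    """Full tracker configuration.

    The default search grid is the symmetric variant: the literal
    0-indexed grid has a nonzero mean displacement (its offsets span
    -0.1..+0.06 of the box extent) which integrates into a systematic
    backward drag over repeated alternations; the symmetric grid keeps
    the same M x N budget and span but centers the offsets, and contains
    a zero-displacement candidate so the coincidence test can terminate
    exactly.
    """

    search: SearchConfig = field(
        default_factory=lambda: SearchConfig(symmetric_grid=True))
    hog: HogConfig = field(default_factory=HogConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    weights: FusionWeights = field(default_factory=FusionWeights)
    update_threshold: float = 0.05
    update_when_greater: bool = False  # comparison direction of the gate
    history_capacity: int = 100
    n_pos_init: int = 50
    n_neg_init: int = 50
    n_regr_init: int = 50


@dataclass
class FrameStats:
    frame_index: int
    alternations: int = 0
    evaluations: int = 0
    naive_evaluations: int = 0
    appearance_change: float = float("nan")
    updated: bool = False
    best_conf: float = float("nan")


@dataclass
class TrackerState:
    box: RotatedRect
    model: HsvmModel
    pools: SamplePools
    history: list[np.ndarray]
    config: TrackerConfig
    rng: np.random.Generator
    frame_index: int = 0
    stats: list[FrameStats] = field(default_factory=list)


def initialize(frame: np.ndarray,
               contour_or_box: RotatedRect | Iterable[Sequence[float]],
               config: TrackerConfig = TrackerConfig(),
               seed: int | np.random.Generator = 0) -> TrackerState:
    """Build the initial tracker state from a marked contour or a box.

    The minimum outer rectangle of the contour becomes the fixed-size
    tracking rectangle; the initial pools are drawn around it (50/50
    binary, 50 regression, the initial patch seeding the one-class pool),
    the three sub-models are trained, and the appearance history starts
    with the initial patch descriptor.
    """
    if isinstance(contour_or_box, RotatedRect):
        box = contour_or_box
    else:
        box = min_outer_rect(contour_or_box)
    thresholds_for(box)  # validates d1 < d2 for this size

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    pools = SamplePools()
    binary = sampling.draw_binary_set(frame, box, config.n_pos_init,
                                      config.n_neg_init, rng, config.hog)
    pools.seed_positive_queue(
        "binary_pos", [s for s in binary if s.label > 0])
    pools.binary_neg = [s for s in binary if s.label <= 0]
    regr = sampling.draw_regression_set(frame, box, config.n_regr_init, rng,
                                        config.hog)
    pools.seed_positive_queue("regr_pos", regr)

    init_feat = hog(extract_patch(frame, box, config.hog), config.hog)
    init_sample = LabeledSample(box, init_feat, SampleRole.ONECLASS, 1.0,
                                reserved=True)
    pools.seed_positive_queue("oneclass", [init_sample])

    model = hsvm_models.train(pools, config.kernel, config.weights)
    return TrackerState(box=box, model=model, pools=pools,
                        history=[init_feat], config=config, rng=rng)


def _score_boxes(state: TrackerState, frame: np.ndarray,
                 boxes: Sequence[RotatedRect]):
    feats = hog_batch(extract_patches(frame, boxes, state.config.hog),
                      state.config.hog)
    return score(state.model, feats)


def angle_step(state: TrackerState, frame: np.ndarray,
               box: RotatedRect | None = None) -> RotatedRect:
    """Best of the 2h+1 rotation candidates around the current box.

    Candidates are ranked with the smallest |angle offset| first so that a
    score tie keeps the unrotated box.
    """
    box = state.box if box is None else box
    cfg = state.config.search
    cands = angle_candidates(box, cfg)
    order = sorted(range(len(cands)),
                   key=lambda i: (abs(i - cfg.h_steps), i - cfg.h_steps))
    ordered = [cands[i] for i in order]
    bundles = _score_boxes(state, frame, ordered)
    return ordered[best_candidate(bundles)]


def shift_step(state: TrackerState, frame: np.ndarray,
               best: RotatedRect) -> RotatedRect:
    """Best of the MxN displacement candidates around ``best`` (row-major)."""
    cands = search_boxes(best, state.config.search)
    bundles = _score_boxes(state, frame, cands)
    return cands[best_candidate(bundles)]


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _coincide_tol_px(box: RotatedRect, cfg: SearchConfig) -> float:
    """Effective coincidence tolerance in pixels.

    The literal displacement grid need not contain a zero offset (with
    M = N = 5 its smallest move is 0.02 x the box extent per axis), so the
    tolerance is floored at just above the smallest move the grid can make;
    otherwise "no more movement" could never be reached.
    """
    e = cfg.m_expand - 1.0
    if cfg.symmetric_grid and cfg.m_cols % 2 == 1 and cfg.n_rows % 2 == 1:
        return cfg.coincide_tol_px
    min_dx = e * box.w * min(abs(i / cfg.m_cols - 0.5) for i in range(cfg.m_cols))
    min_dy = e * box.h * min(abs(j / cfg.n_rows - 0.5) for j in range(cfg.n_rows))
    return max(cfg.coincide_tol_px, 1.05 * math.hypot(min_dx, min_dy))


def track_frame(state: TrackerState, frame: np.ndarray) -> TrackerState:
    """Track one frame: alternate angle and shift searches to coincidence,
    then run the update decision. Mutates and returns ``state``."""
    cfg = state.config.search
    stats = FrameStats(frame_index=state.frame_index + 1)
    tol_px = _coincide_tol_px(state.box, cfg)

    box = state.box
    for _ in range(cfg.max_alternations):
        prev = box
        box = angle_step(state, frame, box)
        box = shift_step(state, frame, box)
        stats.alternations += 1
        stats.evaluations += cfg.evaluations_per_alternation
        stats.naive_evaluations += cfg.naive_evaluations_per_alternation
        moved = math.hypot(box.cx - prev.cx, box.cy - prev.cy)
        turned = _angle_diff(box.a, prev.a)
        if moved <= tol_px and turned <= cfg.coincide_tol_deg:
            break

    state.box = box
    state.frame_index += 1
    state.stats.append(stats)
    maybe_update(state, frame)
    return state


def maybe_update(state: TrackerState, frame: np.ndarray) -> TrackerState:
    """Appearance-gated online update of pools and models.

    Computes the cosine-distance change of the current result descriptor
    against the accepted history; when it passes the gate the pools are
    re-sampled around the result and all three sub-models are retrained.
    The descriptor joins the bounded history either way.
    """
    cfg = state.config
    x_cur = hog(extract_patch(frame, state.box, cfg.hog), cfg.hog)
    d = appearance_change(x_cur, state.history)
    stats = state.stats[-1] if state.stats else None
    if stats is not None:
        stats.appearance_change = d

    accept = (d > cfg.update_threshold if cfg.update_when_greater
              else d < cfg.update_threshold)
    if accept:
        result = LabeledSample(state.box, x_cur, SampleRole.BINARY, 1.0)
        sampling.update_pools(state.pools, result, frame, state.rng, cfg.hog)
        state.model = hsvm_models.train(state.pools, cfg.kernel, cfg.weights)
        if stats is not None:
            stats.updated = True

    state.history.append(x_cur)
    if len(state.history) > cfg.history_capacity:
        del state.history[0]
    return state


def run(frames: Iterable[np.ndarray],
        contour_or_box: RotatedRect | Iterable[Sequence[float]],
        config: TrackerConfig = TrackerConfig(),
        seed: int | np.random.Generator = 0
        ) -> tuple[list[RotatedRect], TrackerState]:
    """Track a whole sequence; frame 0 is the initialization frame and its
    result is the initialization box itself. Returns (boxes, final state)."""
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("empty frame sequence") from None
    state = initialize(first, contour_or_box, config, seed)
    boxes = [state.box]
    for frame in it:
        track_frame(state, frame)
        boxes.append(state.box)
    return boxes, state
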