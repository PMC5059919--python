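"""Training-sample generation for the three SVM sub-models.

Samples are boxes of the same size and orientation as the reference
tracking rectangle, placed at random centers selected by distance rules:
offsets below d1 are positives, offsets in (d1, d2) carry a continuous
overlap-ratio regression target, offsets in (d2, d3) are negatives, and
anything beyond d3 is unused. The thresholds derive from the box size:

    d1 = sqrt(20),  d2 = sqrt(w^2 + h^2) / 2,  d3 = 2 sqrt(w^2 + h^2)

The module also owns the bounded sample pools and the re-sampling rules
applied when the tracker accepts an update: the tracking-result patch is
enqueued FIFO into a 40-slot positive queue whose 10 earliest (initial)
samples are never evicted — the anchor against drift during occlusion —
and the negative sets are redrawn fresh (50 binary, 20 regression).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import RotatedRect, overlap_rate
from .hog_features import HogConfig, extract_patch, hog

__all__ = [
    "SampleRole", "OffsetClass", "SamplingThresholds", "LabeledSample",
    "SamplePools", "thresholds_for", "classify_offset", "draw_binary_set",
    "draw_regression_set", "regression_target", "update_pools",
]


class SampleRole(str, enum.Enum):
    BINARY = "binary"
    REGRESSION = "regression"
    ONECLASS = "oneclass"


class OffsetClass(str, enum.Enum):
    POSITIVE = "positive"
    REGRESSION = "regression"
    NEGATIVE = "negative"
    UNUSED = "unused"


@dataclass(frozen=True)
class SamplingThresholds:
    d1: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        if not (0 < self.d1 < self.d2 < self.d3):
            raise ValueError(
                f"invalid sampling regime: need 0 < d1 < d2 < d3, got "
                f"({self.d1:.3f}, {self.d2:.3f}, {self.d3:.3f}); boxes with "
                f"diagonal < 2*sqrt(20) px are too small to track"
            )


@dataclass
class LabeledSample:
    """An image patch at a box location with its sub-model role and label."""

    box: RotatedRect
    feature: np.ndarray
    role: SampleRole
    label: float = 0.0
    reserved: bool = False


def thresholds_for(box: RotatedRect) -> SamplingThresholds:
    """Distance thresholds for a reference box: (sqrt(20), diag/2, 2*diag)."""
    diag = math.hypot(box.w, box.h)
    return SamplingThresholds(math.sqrt(20.0), diag / 2.0, 2.0 * diag)


def classify_offset(dist: float, th: SamplingThresholds) -> OffsetClass:
    """Classify a center offset distance by the sampling rules."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if dist < th.d1:
        return OffsetClass.POSITIVE
    if th.d1 < dist < th.d2:
        return OffsetClass.REGRESSION
    if th.d2 < dist < th.d3:
        return OffsetClass.NEGATIVE
    return OffsetClass.UNUSED


def regression_target(x0: RotatedRect, xi: RotatedRect) -> float:
    """Overlap-area ratio area(x0 ∩ xi) / area(x0 ∪ xi) — the SVR label."""
    return overlap_rate(x0, xi)


def _check_frame(frame: np.ndarray, ref: RotatedRect, th: SamplingThresholds) -> None:
    h, w = frame.shape[:2]
    if w == 0 or h == 0:
        raise ValueError("frame is empty")
    if (ref.cx < -th.d3 or ref.cx > w + th.d3
            or ref.cy < -th.d3 or ref.cy > h + th.d3):
        raise ValueError("reference box lies too far outside the frame to sample")


def _annulus_centers(ref: RotatedRect, r_in: float, r_out: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """n centers uniform by area in the annulus (r_in, r_out) about ref.c."""
    u = rng.uniform(size=n)
    r = np.sqrt(u * (r_out ** 2 - r_in ** 2) + r_in ** 2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([ref.cx + r * np.cos(phi), ref.cy + r * np.sin(phi)])


def _samples_at(frame: np.ndarray, ref: RotatedRect, centers: np.ndarray,
                role: SampleRole, labels, hog_cfg: HogConfig) -> list[LabeledSample]:
    out = []
    for (x, y), lab in zip(centers, labels):
        box = ref.with_center(float(x), float(y))
        feat = hog(extract_patch(frame, box, hog_cfg), hog_cfg)
        out.append(LabeledSample(box=box, feature=feat, role=role, label=float(lab)))
    return out


def draw_binary_set(frame: np.ndarray, ref: RotatedRect, n_pos: int = 50,
                    n_neg: int = 50, rng: np.random.Generator | None = None,
                    hog_cfg: HogConfig = HogConfig()) -> list[LabeledSample]:
    """Draw the binary training set around ``ref``.

    ``n_pos`` centers uniform in the disc of radius d1 (label +1) and
    ``n_neg`` uniform in the (d2, d3) annulus (label 0), all boxes sharing
    the reference size and angle. Reproducible given the generator state.
    """
    rng = np.random.default_rng() if rng is None else rng
    th = thresholds_for(ref)
    _check_frame(frame, ref, th)
    pos = _samples_at(frame, ref, _annulus_centers(ref, 0.0, th.d1, n_pos, rng),
                      SampleRole.BINARY, np.ones(n_pos), hog_cfg)
    neg = _samples_at(frame, ref, _annulus_centers(ref, th.d2, th.d3, n_neg, rng),
                      SampleRole.BINARY, np.zeros(n_neg), hog_cfg)
    return pos + neg


def draw_regression_set(frame: np.ndarray, ref: RotatedRect, n: int = 50,
                        rng: np.random.Generator | None = None,
                        hog_cfg: HogConfig = HogConfig()) -> list[LabeledSample]:
    """Draw ``n`` regression samples with centers uniform in (d1, d2).

    Labels are the overlap-area ratio of each sample box with ``ref``.
    """
    rng = np.random.default_rng() if rng is None else rng
    th = thresholds_for(ref)
    _check_frame(frame, ref, th)
    centers = _annulus_centers(ref, th.d1, th.d2, n, rng)
    boxes = [ref.with_center(float(x), float(y)) for x, y in centers]
    labels = [regression_target(ref, b) for b in boxes]
    return _samples_at(frame, ref, centers, SampleRole.REGRESSION, labels, hog_cfg)


def _draw_negatives(frame: np.ndarray, ref: RotatedRect, n: int, role: SampleRole,
                    rng: np.random.Generator, hog_cfg: HogConfig,
                    overlap_labels: bool = False) -> list[LabeledSample]:
    th = thresholds_for(ref)
    _check_frame(frame, ref, th)
    centers = _annulus_centers(ref, th.d2, th.d3, n, rng)
    if overlap_labels:
        boxes = [ref.with_center(float(x), float(y)) for x, y in centers]
        labels = [regression_target(ref, b) for b in boxes]
    else:
        labels = np.zeros(n)
    return _samples_at(frame, ref, centers, role, labels, hog_cfg)


@dataclass
class SamplePools:
    """Bounded sample pools for the three sub-models.

    ``binary_pos``, ``regr_pos`` and ``oneclass`` are FIFO queues capped at
    ``pos_capacity`` whose first ``n_reserved`` entries (the initial samples)
    are never evicted; ``binary_neg`` and ``regr_neg`` are replaced wholesale
    at each update.
    """

    binary_pos: list[LabeledSample] = field(default_factory=list)
    binary_neg: list[LabeledSample] = field(default_factory=list)
    regr_pos: list[LabeledSample] = field(default_factory=list)
    regr_neg: list[LabeledSample] = field(default_factory=list)
    oneclass: list[LabeledSample] = field(default_factory=list)
    pos_capacity: int = 40
    n_reserved: int = 10
    binary_neg_size: int = 50
    regr_neg_size: int = 20

    def _enqueue(self, queue: list[LabeledSample], sample: LabeledSample) -> None:
        queue.append(sample)
        if len(queue) > self.pos_capacity:
            for i, s in enumerate(queue):
                if not s.reserved:
                    del queue[i]
                    break
            else:  # pragma: no cover - capacity > reserved always holds
                del queue[-1]

    def seed_positive_queue(self, queue_name: str,
                            samples: list[LabeledSample]) -> None:
        """Fill a positive queue with the initial draws, marking the earliest
        ``n_reserved`` as permanently reserved and capping at capacity."""
        queue = getattr(self, queue_name)
        for i, s in enumerate(samples):
            s.reserved = i < self.n_reserved
            self._enqueue(queue, s)

    def push_result(self, binary: LabeledSample, regression: LabeledSample,
                    oneclass: LabeledSample) -> None:
        self._enqueue(self.binary_pos, binary)
        self._enqueue(self.regr_pos, regression)
        self._enqueue(self.oneclass, oneclass)


def update_pools(pools: SamplePools, new_result: LabeledSample, frame: np.ndarray,
                 rng: np.random.Generator | None = None,
                 hog_cfg: HogConfig = HogConfig()) -> SamplePools:
    """Apply the re-sampling rules for an accepted tracking result.

    The result patch enters all three positive queues FIFO (reserved
    initial samples are immune to eviction); the binary negatives are
    replaced by 50 fresh draws and the regression negatives by 20, both
    around the new result's box.
    """
    rng = np.random.default_rng() if rng is None else rng
    box, feat = new_result.box, new_result.feature
    pools.push_result(
        LabeledSample(box, feat, SampleRole.BINARY, 1.0),
        LabeledSample(box, feat, SampleRole.REGRESSION, 1.0),
        LabeledSample(box, feat, SampleRole.ONECLASS, 1.0),
    )
    pools.binary_neg = _draw_negatives(frame, box, pools.binary_neg_size,
                                       SampleRole.BINARY, rng, hog_cfg)
    pools.regr_neg = _draw_negatives(frame, box, pools.regr_neg_size,
                                     SampleRole.REGRESSION, rng, hog_cfg,
                                     overlap_labels=True)
    return pools
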