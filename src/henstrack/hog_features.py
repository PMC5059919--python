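"""Histogram-of-orientation-gradients descriptors of rotated regions.

Every sample and candidate region the tracker scores is an oriented
rectangle whose content is rectified to an axis-aligned patch, normalized
to a fixed square window (16x16 by default), and described by a
block-normalized HOG vector. The cosine-distance change measure computed
on those descriptors drives the online update decision.

The descriptor geometry is fixed by the tracker design: a 16x16 window,
4x4 cells, blocks of 2x2 cells strided one cell, 9 unsigned orientation
bins — a 3x3 grid of blocks, 36 values each, 324 values in total.
Gradients are centered differences with edge replication; orientations
are binned hard (no interpolation); each block is plain L2-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize

from .geometry import RotatedRect

__all__ = ["HogConfig", "extract_patch", "extract_patches", "hog", "hog_batch",
           "appearance_change"]

# Rec.601 luminance weights for color frames
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HogConfig:
    """Descriptor geometry: window/cell sizes in pixels, block layout, bins."""

    win: int = 16
    cell: int = 4
    block_cells: int = 4
    stride_cells: int = 1
    orientations: int = 9

    def __post_init__(self) -> None:
        if self.win % self.cell != 0:
            raise ValueError("window size must be divisible by cell size")
        b = int(round(math.sqrt(self.block_cells)))
        if b * b != self.block_cells:
            raise ValueError("block_cells must be a perfect square (2x2 etc.)")
        if self.stride_cells != 1:
            raise ValueError("only 1-cell block stride is supported")
        if self.orientations < 1:
            raise ValueError("need at least one orientation bin")

    @property
    def cells_per_side(self) -> int:
        return self.win // self.cell

    @property
    def block_side(self) -> int:
        return int(round(math.sqrt(self.block_cells)))

    @property
    def blocks_per_side(self) -> int:
        return self.cells_per_side - self.block_side + 1

    @property
    def length(self) -> int:
        """Descriptor length; 324 at the default geometry."""
        return self.blocks_per_side ** 2 * self.block_cells * self.orientations


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.asarray(frame, dtype=float)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return np.asarray(frame[..., :3], dtype=float) @ _LUMA
    raise ValueError(f"expected a 2-D or HxWx3 image, got shape {frame.shape}")


def extract_patch(frame: np.ndarray, box: RotatedRect,
                  cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Rectify the oriented box content into a win x win intensity patch.

    The box interior is inverse-rotated into an axis-aligned w x h patch by
    bilinear sampling (edge replication outside the frame), then resized to
    the descriptor window by bilinear interpolation. Color frames are
    converted to luminance first.
    """
    gray = _to_gray(frame)
    if gray.size == 0:
        raise ValueError("frame is empty")
    w_r = max(1, int(round(box.w)))
    h_r = max(1, int(round(box.h)))
    theta = math.radians(box.a)
    c, s = math.cos(theta), math.sin(theta)
    # local sample coordinates at sub-pixel cell centers across the box
    u = (np.arange(w_r) + 0.5) / w_r * box.w - box.w / 2.0
    v = (np.arange(h_r) + 0.5) / h_r * box.h - box.h / 2.0
    uu, vv = np.meshgrid(u, v)
    xs = uu * c - vv * s + box.cx
    ys = uu * s + vv * c + box.cy
    rect = map_coordinates(gray, [ys, xs], order=1, mode="nearest")
    if rect.shape == (cfg.win, cfg.win):
        return rect
    # Gaussian prefilter before downsampling: without it, aliasing makes the
    # descriptor jump under sub-pixel motion and sensor noise
    return resize(rect, (cfg.win, cfg.win), order=1, mode="edge",
                  anti_aliasing=True, preserve_range=True)


def extract_patches(frame: np.ndarray, boxes: Sequence[RotatedRect],
                    cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Stack of rectified patches for a batch of boxes, shape (n, win, win)."""
    return np.stack([extract_patch(frame, b, cfg) for b in boxes])


def hog_batch(patches: np.ndarray, cfg: HogConfig = HogConfig()) -> np.ndarray:
    """HOG descriptors for a stack of win x win patches, shape (n, length)."""
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    n, ph, pw = patches.shape
    if (ph, pw) != (cfg.win, cfg.win):
        raise ValueError(f"patches must be {cfg.win}x{cfg.win}, got {ph}x{pw}")

    pad = np.pad(patches, ((0, 0), (1, 1), (1, 1)), mode="edge")
    gx = pad[:, 1:-1, 2:] - pad[:, 1:-1, :-2]
    gy = pad[:, 2:, 1:-1] - pad[:, :-2, 1:-1]
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0  # unsigned orientations

    nb = cfg.orientations
    bins = np.minimum((ang / (180.0 / nb)).astype(int), nb - 1)

    nc = cfg.cells_per_side
    cell = cfg.cell
    # per-cell orientation histograms, magnitude-weighted hard assignment
    hist = np.zeros((n, nc, nc, nb))
    for b in range(nb):
        m = np.where(bins == b, mag, 0.0)
        hist[..., b] = m.reshape(n, nc, cell, nc, cell).sum(axis=(2, 4))

    bs = cfg.block_side
    nblk = cfg.blocks_per_side
    out = np.empty((n, cfg.length))
    k = cfg.block_cells * nb
    idx = 0
    for by in range(nblk):
        for bx in range(nblk):
            block = hist[:, by:by + bs, bx:bx + bs, :].reshape(n, k)
            norm = np.sqrt((block ** 2).sum(axis=1, keepdims=True))
            out[:, idx:idx + k] = np.where(norm > 0, block / np.maximum(norm, 1e-12), 0.0)
            idx += k
    return out


def hog(patch: np.ndarray, cfg: HogConfig = HogConfig()) -> np.ndarray:
    """HOG descriptor of a single win x win patch (1-D, non-negative)."""
    return hog_batch(patch[None] if patch.ndim == 2 else patch, cfg)[0]


def appearance_change(x_cur: np.ndarray, history: Sequence[np.ndarray]) -> float:
    """One minus the best cosine similarity of ``x_cur`` to any past descriptor.

    Small values mean the current result still looks like a previously
    accepted appearance; the tracker only retrains when this change measure
    stays below its update threshold. Zero-norm vectors contribute
    similarity 0 by convention.
    """
    if len(history) == 0:
        raise ValueError("appearance history is empty")
    x = np.asarray(x_cur, dtype=float)
    nx = np.linalg.norm(x)
    best = 0.0
    for xj in history:
        xj = np.asarray(xj, dtype=float)
        if xj.shape != x.shape:
            raise ValueError("history descriptor length mismatch")
        nj = np.linalg.norm(xj)
        if nx > 0 and nj > 0:
            best = max(best, float(x @ xj) / (nx * nj))
    return float(min(max(1.0 - best, 0.0), 1.0))
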