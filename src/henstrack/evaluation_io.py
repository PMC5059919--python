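"""Overlap-rate evaluation and file formats.

The tracking quality metric is the overlap rate (rotated-box
intersection-over-union) of the tracked box against ground truth, per
frame; a rate of 0 means the target was completely lost. Reports carry
the per-frame records, the arithmetic mean overlap per scenario tag, the
overall mean, and the lost-frame count.

Rotated-box tracks serialize as CSV with columns
``frame,cx,cy,w,h,a_deg`` (angle in degrees); this dialect is shared by
tracker output, ground truth and the synthetic generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import RotatedRect, overlap_rate

__all__ = ["TrackRecord", "EvalReport", "evaluate", "write_track",
           "read_track", "read_truth", "read_tags", "write_tags",
           "write_report", "plot_overlap_curve"]

_COLUMNS = ["frame", "cx", "cy", "w", "h", "a_deg"]


@dataclass(frozen=True)
class TrackRecord:
    frame: int
    result: RotatedRect
    truth: RotatedRect
    or_value: float
    tag: str


@dataclass(frozen=True)
class EvalReport:
    per_frame: tuple[TrackRecord, ...]
    mean_or_by_tag: dict[str, float]
    mean_or_all: float
    loss_frames: int

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)


def evaluate(track: Sequence[RotatedRect], truth: Sequence[RotatedRect],
             tags: Sequence[str] | None = None) -> EvalReport:
    """Per-frame overlap rates plus tag-wise and overall arithmetic means.

    Lost frames (overlap exactly 0) are included in every mean.
    """
    if len(track) != len(truth):
        raise ValueError(f"track has {len(track)} frames but truth has {len(truth)}")
    if len(track) == 0:
        raise ValueError("cannot evaluate an empty track")
    if tags is None:
        tags = ["all"] * len(track)
    elif len(tags) != len(track):
        raise ValueError("tags length must match the track")

    records = tuple(
        TrackRecord(i, rt, rl, overlap_rate(rt, rl), str(tag))
        for i, (rt, rl, tag) in enumerate(zip(track, truth, tags))
    )
    by_tag: dict[str, list[float]] = {}
    for rec in records:
        by_tag.setdefault(rec.tag, []).append(rec.or_value)
    return EvalReport(
        per_frame=records,
        mean_or_by_tag={t: float(np.mean(v)) for t, v in by_tag.items()},
        mean_or_all=float(np.mean([r.or_value for r in records])),
        loss_frames=sum(1 for r in records if r.or_value == 0.0),
    )


def write_track(path, boxes: Sequence[RotatedRect],
                frames: Sequence[int] | None = None) -> None:
    """Write boxes as the shared CSV dialect (fixed 6-decimal formatting,
    byte-stable for identical input)."""
    if frames is None:
        frames = range(len(boxes))
    lines = [",".join(_COLUMNS)]
    for f, b in zip(frames, boxes):
        lines.append(f"{int(f)},{b.cx:.6f},{b.cy:.6f},{b.w:.6f},{b.h:.6f},{b.a:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_boxes(path) -> tuple[list[int], list[RotatedRect]]:
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty track file")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frames, boxes = [], []
    for idx, row in df.iterrows():
        vals = [row[c] for c in _COLUMNS]
        if any(pd.isna(v) for v in vals):
            raise ValueError(f"{path}: malformed row at line {idx + 2}")
        try:
            boxes.append(RotatedRect(float(row.cx), float(row.cy),
                                     float(row.w), float(row.h),
                                     float(row.a_deg)))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid box at line {idx + 2}: {exc}") from exc
        frames.append(int(row.frame))
    return frames, boxes


def read_track(path) -> list[RotatedRect]:
    return _read_boxes(path)[1]


read_truth = read_track


def read_tags(path) -> list[str]:
    df = pd.read_csv(path)
    if "tag" not in df.columns:
        raise ValueError(f"{path}: tags CSV needs a 'tag' column")
    return [str(t) for t in df["tag"]]


def write_tags(path, tags: Sequence[str]) -> None:
    lines = ["frame,tag"] + [f"{i},{t}" for i, t in enumerate(tags)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: EvalReport, out_dir) -> None:
    """Write report.csv (one row per scenario plus all_frames) and report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tag in sorted(report.mean_or_by_tag):
        n = sum(1 for r in report.per_frame if r.tag == tag)
        loss = sum(1 for r in report.per_frame if r.tag == tag and r.or_value == 0)
        rows.append({"scenario": tag, "mean_overlap_rate": report.mean_or_by_tag[tag],
                     "n_frames": n, "loss_frames": loss})
    rows.append({"scenario": "all_frames", "mean_overlap_rate": report.mean_or_all,
                 "n_frames": report.n_frames, "loss_frames": report.loss_frames})
    pd.DataFrame(rows).to_csv(out / "report.csv", index=False, float_format="%.6f")

    payload = {
        "mean_or_by_tag": report.mean_or_by_tag,
        "mean_or_all": report.mean_or_all,
        "loss_frames": report.loss_frames,
        "n_frames": report.n_frames,
        "per_frame_or": [r.or_value for r in report.per_frame],
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")


def plot_overlap_curve(report: EvalReport, path) -> None:
    """Per-frame overlap-rate curve (success-plot style)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot([r.frame for r in report.per_frame],
            [r.or_value for r in report.per_frame], lw=1.2)
    ax.set_xlabel("frame")
    ax.set_ylabel("overlap rate")
    ax.set_ylim(-0.02, 1.02)
    ax.axhline(0.0, color="0.7", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
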