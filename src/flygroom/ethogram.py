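"""Behavior-interval segmentation of the per-frame prediction stream.

Fly grooming bouts last at least half a second, so a class change in the
frame-wise predictions is only accepted once the new class persists for
10 consecutive frames (0.4 s at 25 fps).  On confirmation the previous
interval is closed at the frame before the confirming run began and the
new interval's start is backed off to the first frame of that run, so
the recorded start time includes the 10 frames that already happened.
Runs shorter than the persistence threshold — occasional distorted
feature images or classifier errors — are absorbed into the surrounding
interval.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classifier import FramePrediction
from .dataset import BEHAVIOR_CLASSES, CLASS_TO_ID

__all__ = ["SegmenterConfig", "BehaviorInterval", "segment", "segment_labels",
           "write_intervals", "read_intervals"]


@dataclass(frozen=True)
class SegmenterConfig:
    persistence_frames: int = 10  #: consecutive frames confirming a class change
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class BehaviorInterval:
    """One behavior bout: class plus inclusive frame bounds."""

    behavior: str
    start_frame: int
    end_frame: int
    fps: float = 25.0

    @property
    def start_s(self) -> float:
        return self.start_frame / self.fps

    @property
    def end_s(self) -> float:
        return self.end_frame / self.fps

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame + 1) / self.fps

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def segment_labels(
    labels: Sequence[int | str],
    cfg: SegmenterConfig | None = None,
    first_index: int = 0,
) -> list[BehaviorInterval]:
    """Segment a contiguous stream of per-frame class labels.

    ``labels[i]`` is the prediction for absolute frame ``first_index + i``;
    entries may be class ids or class names.
    """
    if cfg is None:
        cfg = SegmenterConfig()
    ids = [CLASS_TO_ID[l] if isinstance(l, str) else int(l) for l in labels]
    n = len(ids)
    p = cfg.persistence_frames
    intervals: list[BehaviorInterval] = []
    current: int | None = None       # class of the open interval
    current_start = 0
    challenger: int | None = None    # candidate class of a pending run
    run_start = 0
    run_len = 0

    def close(end: int) -> None:
        if current is not None:
            intervals.append(
                BehaviorInterval(
                    behavior=BEHAVIOR_CLASSES[current],
                    start_frame=current_start + first_index,
                    end_frame=end + first_index,
                    fps=cfg.fps,
                )
            )

    for t, c in enumerate(ids):
        if c == current:
            challenger, run_len = None, 0
            continue
        if c == challenger:
            run_len += 1
        else:
            challenger, run_start, run_len = c, t, 1
        if run_len >= p:
            close(run_start - 1)
            current, current_start = challenger, run_start
            challenger, run_len = None, 0
    close(n - 1)
    return intervals


def segment(
    preds: Sequence[FramePrediction],
    cfg: SegmenterConfig | None = None,
) -> list[BehaviorInterval]:
    """Segment classifier predictions into behavior intervals.

    Predictions must be sorted by ``window_index`` and contiguous (one
    per frame); gaps indicate a partial extraction and raise.
    """
    if cfg is None:
        cfg = SegmenterConfig()
    if not preds:
        return []
    indices = [p.window_index for p in preds]
    for a, b in zip(indices, indices[1:]):
        if b != a + 1:
            raise ValueError(
                f"prediction stream has a gap between frames {a} and {b}; "
                "re-extract features over the full video"
            )
    return segment_labels([p.label for p in preds], cfg, first_index=indices[0])


def write_intervals(intervals: Sequence[BehaviorInterval], path: str | Path) -> None:
    """Write intervals as CSV with 2-decimal second columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["behavior", "start_frame", "end_frame", "start_s", "end_s", "duration_s"]
        )
        for iv in intervals:
            writer.writerow(
                [
                    iv.behavior,
                    iv.start_frame,
                    iv.end_frame,
                    f"{iv.start_s:.2f}",
                    f"{iv.end_s:.2f}",
                    f"{iv.duration_s:.2f}",
                ]
            )


def read_intervals(path: str | Path, fps: float = 25.0) -> list[BehaviorInterval]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                BehaviorInterval(
                    behavior=row["behavior"],
                    start_frame=int(row["start_frame"]),
                    end_frame=int(row["end_frame"]),
                    fps=fps,
                )
            )
    return out
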