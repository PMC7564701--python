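"""Summary statistics over detected behavior intervals.

Covers the bookkeeping reported for a detection campaign: per-video
accuracy records, the cohort mean / dispersion / per-video deviances,
and the *difference degree* — the fraction of manually counted behaviors
on which an automatic run disagrees with the human observer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ethogram import BehaviorInterval

__all__ = [
    "VideoResult",
    "CohortSummary",
    "summarize",
    "difference_degree",
    "compare_to_reference",
]


@dataclass(frozen=True)
class VideoResult:
    """Verified detection outcome for one video."""

    video_id: str
    n_behaviors: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_behaviors:
            raise ValueError(
                f"n_correct must lie in [0, n_behaviors]: {self.n_correct}/{self.n_behaviors}"
            )

    @property
    def accuracy(self) -> float:
        """Percent of detected behaviors verified correct."""
        if self.n_behaviors == 0:
            return 0.0
        return 100.0 * self.n_correct / self.n_behaviors


@dataclass(frozen=True)
class CohortSummary:
    """Cross-video aggregate of verified accuracies."""

    total_behaviors: int
    mean_accuracy: float     #: unweighted mean of per-video accuracies, percent
    dispersion: float        #: population SD (ddof=0) of the accuracies, percent
    deviances: tuple[float, ...]  #: per-video accuracy minus the mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total_behaviors": [self.total_behaviors],
                "mean_accuracy": [self.mean_accuracy],
                "dispersion": [self.dispersion],
            }
        )


def summarize(results: Sequence[VideoResult]) -> CohortSummary:
    """Aggregate per-video accuracies across a cohort of individuals.

    The dispersion is the population standard deviation (divide by n)
    of the per-video accuracy percentages; deviances are each video's
    accuracy minus the cohort mean and sum to zero by construction.
    """
    if not results:
        raise ValueError("cannot summarize an empty result list")
    acc = np.array([r.accuracy for r in results], dtype=np.float64)
    mean = float(acc.mean())
    return CohortSummary(
        total_behaviors=int(sum(r.n_behaviors for r in results)),
        mean_accuracy=mean,
        dispersion=float(acc.std(ddof=0)),
        deviances=tuple(float(a - mean) for a in acc),
    )


def difference_degree(n_diff: int, n_manual: int) -> float:
    """Percent of manually counted behaviors where the automatic result
    differs, rounded to two decimals."""
    if n_manual <= 0:
        raise ValueError("manual behavior count must be positive")
    if n_diff < 0:
        raise ValueError("difference count cannot be negative")
    return round(100.0 * n_diff / n_manual, 2)


def _overlaps(a: BehaviorInterval, b: BehaviorInterval) -> bool:
    return max(a.start_frame, b.start_frame) <= min(a.end_frame, b.end_frame)


def compare_to_reference(
    detected: Sequence[BehaviorInterval],
    reference: Sequence[BehaviorInterval],
    tol_frames: int = 15,
) -> int:
    """Count disagreements between a detected track and a reference track.

    One difference is charged per reference behavior when any of these
    hold: the span is covered by a number of detected intervals other
    than one (missed or split behavior); the single overlapping detected
    interval has a different class; or either boundary deviates by more
    than ``tol_frames`` frames.
    """
    n_diff = 0
    for ref in reference:
        hits = [d for d in detected if _overlaps(d, ref)]
        if len(hits) != 1:
            n_diff += 1
            continue
        d = hits[0]
        if (
            d.behavior != ref.behavior
            or abs(d.start_frame - ref.start_frame) > tol_frames
            or abs(d.end_frame - ref.end_frame) > tol_frames
        ):
            n_diff += 1
    return n_diff
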