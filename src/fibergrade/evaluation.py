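"""Evaluation of extracted fibers against synthetic ground truth.

Matching is by centerline proximity: an extracted trace matches a true
(straight) fiber when the mean perpendicular distance of its centerline
points to the true segment is below a tolerance and the axial orientations
agree. Matches are greedy one-to-one in input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fibers import FiberTrace
from .synthetic import FiberGroundTruth

__all__ = ["RecoveryStats", "match_to_ground_truth"]


@dataclass(frozen=True)
class RecoveryStats:
    n_true: int
    n_extracted: int
    n_matched: int
    length_rel_errors: tuple[float, ...]

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_extracted if self.n_extracted else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0

    @property
    def median_length_error(self) -> float:
        if not self.length_rel_errors:
            return float("nan")
        return float(np.median(self.length_rel_errors))

    def pooled_with(self, other: "RecoveryStats") -> "RecoveryStats":
        return RecoveryStats(
            n_true=self.n_true + other.n_true,
            n_extracted=self.n_extracted + other.n_extracted,
            n_matched=self.n_matched + other.n_matched,
            length_rel_errors=self.length_rel_errors + other.length_rel_errors,
        )


def _mean_distance_to_segment(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> float:
    seg = p1 - p0
    length = float(np.hypot(*seg))
    if length == 0.0:
        return float(np.mean(np.hypot(*(points - p0).T)))
    rel = points - p0
    perp = np.abs(rel[:, 0] * seg[1] - rel[:, 1] * seg[0]) / length
    t = (rel @ seg) / (length * length)
    # points projecting far off the segment count as non-matching
    perp = np.where((t >= -0.05) & (t <= 1.05), perp, np.inf)
    return float(np.mean(perp))


def _axial_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def match_to_ground_truth(
    extracted: Sequence[FiberTrace],
    truth: FiberGroundTruth,
    distance_tol_px: float = 4.0,
    angle_tol_deg: float = 10.0,
    min_true_length_um: float = 5.3,
) -> RecoveryStats:
    """Greedy one-to-one match of extracted traces to valid true fibers."""
    true_fibers = [f for f in truth.fibers if f.length_um > min_true_length_um]
    used: set[int] = set()
    matched = 0
    errors: list[float] = []
    for trace in extracted:
        best: tuple[float, int] | None = None
        for i, g in enumerate(true_fibers):
            if i in used:
                continue
            d = _mean_distance_to_segment(trace.centerline, g.points[0], g.points[-1])
            if d < distance_tol_px and _axial_diff(
                trace.orientation_deg, g.orientation_deg
            ) < angle_tol_deg:
                if best is None or d < best[0]:
                    best = (d, i)
        if best is not None:
            used.add(best[1])
            matched += 1
            g = true_fibers[best[1]]
            errors.append(abs(trace.length_um - g.length_um) / g.length_um)
    return RecoveryStats(
        n_true=len(true_fibers),
        n_extracted=len(extracted),
        n_matched=matched,
        length_rel_errors=tuple(errors),
    )
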