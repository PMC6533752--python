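"""Per-ROI collagen measures: density, alignment, intensity fraction.

Density is the raw count of valid fibers in the ROI (ROIs have constant
area, so counts and areal densities are proportional). Alignment is the
mean resultant vector length of the *doubled* axial orientations — fibers
are undirected, so angles live modulo 180 degrees and the standard axial
treatment maps them to the full circle before averaging. R ranges from 0
(no preferred axis; e.g. an even mix of perpendicular fibers) to 1 (all
fibers parallel). Alignment is reported as missing (None) for ROIs with
fewer than ``n_min`` valid fibers (default 20), never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fibers import FiberTrace

__all__ = [
    "ROIMetrics",
    "collagen_density",
    "alignment_coefficient",
    "intensity_density",
    "orientation_histogram",
]

DEFAULT_N_MIN = 20


@dataclass(frozen=True)
class ROIMetrics:
    n_valid_fibers: int
    alignment_R: float | None
    intensity_fraction: float

    def __post_init__(self) -> None:
        if self.alignment_R is not None and not (0.0 <= self.alignment_R <= 1.0 + 1e-12):
            raise ValueError(f"alignment_R out of [0, 1]: {self.alignment_R}")
        if not (0.0 <= self.intensity_fraction <= 1.0):
            raise ValueError(f"intensity_fraction out of [0, 1]: {self.intensity_fraction}")


def collagen_density(valid_fibers: Sequence[FiberTrace]) -> int:
    """Number of valid fibers in the ROI (fibers must already have passed the
    length filter)."""
    return len(valid_fibers)


def alignment_coefficient(
    orientations_deg: Sequence[float] | np.ndarray,
    n_min: int = DEFAULT_N_MIN,
) -> float | None:
    """Mean resultant vector length of doubled axial angles.

    R = (1/n) * sqrt((sum cos 2theta)^2 + (sum sin 2theta)^2).

    Returns None when fewer than ``n_min`` orientations are supplied (the
    minimum-fiber rule for a statistically meaningful estimate). Angles
    outside [0, 180) are normalized modulo 180 with a warning; this never
    changes R, since doubling maps theta and theta+180 to the same point.
    """
    theta = np.asarray(orientations_deg, dtype=float)
    if theta.ndim != 1:
        theta = theta.ravel()
    if len(theta) < n_min:
        return None
    if np.any((theta < 0.0) | (theta >= 180.0)):
        warnings.warn("orientations outside [0, 180) normalized modulo 180")
        theta = np.mod(theta, 180.0)
    d = np.deg2rad(2.0 * theta)
    r = float(np.hypot(np.cos(d).sum(), np.sin(d).sum()) / len(theta))
    return min(r, 1.0)


def intensity_density(roi_image: np.ndarray, mask: np.ndarray) -> float:
    """Foreground ("white") pixel fraction of the ROI: the intensity-based
    density cross-check."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.sum() / mask.size)


def orientation_histogram(
    orientations_deg: Sequence[float] | np.ndarray, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """QC histogram of axial orientations over [0, 180) (default 10-degree
    bins). Returns (counts, bin_edges)."""
    theta = np.mod(np.asarray(orientations_deg, dtype=float), 180.0)
    return np.histogram(theta, bins=n_bins, range=(0.0, 180.0))
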