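"""Data model for TMA cores, ROI annotations, observations and configuration.

Coordinate conventions: all rectangles are 0-based, half-open
[x0, x1) x [y0, y1), row-major images with the origin at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

GRADES = ("grade1", "grade4")
DEFAULT_ROI_SIZE_HE_PX = 400  # 400 px at 0.505 um/px = 202 um


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ROIAnnotation:
    """One annotated rectangle, in H&E ("he") or SHG ("shg") pixel space."""

    roi_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    space: str = "he"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.space not in ("he", "shg"):
            raise ModelValidationError(f"space must be 'he' or 'shg', got {self.space!r}")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ModelValidationError(
                f"ROI {self.roi_id}: empty rectangle [{self.x0},{self.x1})x[{self.y0},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass
class TMACore:
    """One patient's core: grade label, image references, ROI set, exclusion."""

    core_id: str
    patient_id: str
    grade: str
    shg_image_ref: Path
    he_image_ref: Path | None = None
    rois: tuple[ROIAnnotation, ...] = ()
    excluded: bool = False
    exclusion_reason: str | None = None
    true_transform: list | None = None  # synthetic ground truth, if any

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ModelValidationError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if not (2 <= len(self.rois) <= 3) and len(self.rois) != 0:
            raise ModelValidationError(
                f"core {self.core_id}: expected 2-3 ROIs, got {len(self.rois)}"
            )


@dataclass(frozen=True)
class ObservationRow:
    """Long-format row for the mixed model: one ROI of one patient."""

    patient_id: str
    g: int  # 1 = grade 4
    core_id: str
    roi_id: str
    density: int
    alignment: float | None
    intensity_fraction: float

    def __post_init__(self) -> None:
        if self.g not in (0, 1):
            raise ModelValidationError(f"grade indicator must be 0 or 1, got {self.g}")
        if self.density < 0:
            raise ModelValidationError(f"density must be nonnegative, got {self.density}")


@dataclass
class PipelineConfig:
    """Pipeline thresholds and settings.

    The fiber validity threshold is given both in pixels and micrometres
    ("longer than 5.3 um, or 30 pixels"); the two must agree through the SHG
    pixel size within 2%.
    """

    min_fiber_length_px: int = 30
    min_fiber_length_um: float = 5.3
    n_min_alignment: int = 20
    shg_pixel_size_um: float = 0.1767
    he_pixel_size_um: float = 0.505
    no_signal_foreground_fraction: float = 0.001
    binarization: str = "otsu"
    fiber_width_um: float = 1.0
    registration_model: str = "similarity"
    # whole-core registration runs at half resolution (pyramid factors 4
    # and 2) with translation-only fine polish: a few SHG px (~1 um) of
    # ROI-mapping error, negligible against a 600 px ROI, at a fraction of
    # the full-resolution cost
    registration_levels: int = 2
    registration_finest_factor: float = 2.0
    drop_alignment_per_core: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        implied = self.min_fiber_length_px * self.shg_pixel_size_um
        if abs(implied - self.min_fiber_length_um) > 0.02 * self.min_fiber_length_um:
            raise ModelValidationError(
                f"min_fiber_length_um={self.min_fiber_length_um} inconsistent with "
                f"{self.min_fiber_length_px} px x {self.shg_pixel_size_um} um/px = {implied:.3f}"
            )
        if self.binarization not in ("otsu", "fixed"):
            raise ModelValidationError(f"unknown binarization {self.binarization!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)


def load_manifest(path: str | Path) -> tuple[list[TMACore], dict]:
    """Read a ``cores.json`` manifest into TMACore objects plus metadata.

    Image paths in the manifest are resolved relative to the manifest file.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    base = path.parent
    cores: list[TMACore] = []
    seen_ids: set[str] = set()
    for c in data["cores"]:
        if c["core_id"] in seen_ids:
            raise ModelValidationError(f"duplicate core_id {c['core_id']!r} in manifest")
        seen_ids.add(c["core_id"])
        rois = tuple(
            ROIAnnotation(
                roi_id=r["roi_id"],
                x0=r["x0"],
                y0=r["y0"],
                x1=r["x1"],
                y1=r["y1"],
                space=r.get("space", "he"),
            )
            for r in c["rois"]
        )
        cores.append(
            TMACore(
                core_id=c["core_id"],
                patient_id=c["patient_id"],
                grade=c["grade"],
                shg_image_ref=base / c["shg_path"],
                he_image_ref=(base / c["he_path"]) if c.get("he_path") else None,
                rois=rois,
                true_transform=c.get("true_transform"),
            )
        )
    meta = {k: v for k, v in data.items() if k != "cores"}
    return cores, meta
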