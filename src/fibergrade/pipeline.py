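"""Pipeline orchestration: stitching, cropping, exclusion, observation table,
and the end-to-end run from a cohort manifest to the grade comparison."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import fibers as fx
from . import metrics as mx
from . import registration as rg
from . import stats as st
from .model import ObservationRow, PipelineConfig, ROIAnnotation, TMACore
from .transforms import AffineTransform2D

logger = logging.getLogger("fibergrade")

__all__ = [
    "stitch_tiles",
    "crop_roi",
    "exclude_no_signal_cores",
    "build_observation_table",
    "run_pipeline",
    "PipelineResult",
]


def stitch_tiles(
    tiles: Sequence[np.ndarray], offsets: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Place tiles at integer (x, y) offsets on the bounding-box canvas.

    Overlapping pixels take the mean of all contributing tiles. All offsets
    must be nonnegative (tiles within the canvas); tile dtypes must agree.
    """
    if len(tiles) == 0:
        raise ValueError("empty tile list")
    if len(tiles) != len(offsets):
        raise ValueError("tiles and offsets must have equal length")
    dtypes = {t.dtype for t in tiles}
    if len(dtypes) > 1:
        raise ValueError(f"mismatched tile dtypes: {sorted(map(str, dtypes))}")
    for ox, oy in offsets:
        if ox < 0 or oy < 0:
            raise ValueError("offsets must place every tile within the canvas (nonnegative)")
    h = max(t.shape[0] + oy for t, (ox, oy) in zip(tiles, offsets))
    w = max(t.shape[1] + ox for t, (ox, oy) in zip(tiles, offsets))
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int32)
    for t, (ox, oy) in zip(tiles, offsets):
        acc[oy : oy + t.shape[0], ox : ox + t.shape[1]] += t
        cnt[oy : oy + t.shape[0], ox : ox + t.shape[1]] += 1
    out = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    src_dtype = tiles[0].dtype
    if np.issubdtype(src_dtype, np.integer):
        return np.rint(out).astype(src_dtype)
    return out.astype(src_dtype)


def crop_roi(image: np.ndarray, roi: ROIAnnotation) -> np.ndarray:
    """Exact half-open crop of an SHG-space ROI; rectangles partially outside
    the image are clipped with a logged warning."""
    if roi.space != "shg":
        raise ValueError(f"crop_roi expects an SHG-space ROI, got space={roi.space!r}")
    h, w = image.shape[:2]
    x0, x1 = max(roi.x0, 0), min(roi.x1, w)
    y0, y1 = max(roi.y0, 0), min(roi.y1, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"ROI {roi.roi_id} does not intersect the image")
    if (x0, y0, x1, y1) != (roi.x0, roi.y0, roi.x1, roi.y1):
        logger.warning(
            "ROI %s clipped to image bounds: [%d,%d)x[%d,%d) -> [%d,%d)x[%d,%d)",
            roi.roi_id, roi.x0, roi.x1, roi.y0, roi.y1, x0, x1, y0, y1,
        )
    return image[y0:y1, x0:x1]


def _extraction_config(config: PipelineConfig) -> fx.ExtractionConfig:
    return fx.ExtractionConfig(
        pixel_size_um=config.shg_pixel_size_um,
        fiber_width_um=config.fiber_width_um,
        min_length_um=config.min_fiber_length_um,
        min_length_px=config.min_fiber_length_px,
        binarization=config.binarization,
    )


def exclude_no_signal_cores(
    cores: Sequence[TMACore],
    config: PipelineConfig,
) -> tuple[list[TMACore], list[TMACore]]:
    """Partition cores into (retained, excluded) by the no-signal rule: a core
    is excluded when its foreground fraction (after band-pass preprocessing
    and noise-floored binarization) falls below
    ``config.no_signal_foreground_fraction``. Unreadable images are excluded
    with an explicit error reason rather than dropped."""
    ext_cfg = _extraction_config(config)
    retained: list[TMACore] = []
    excluded: list[TMACore] = []
    for core in cores:
        try:
            img = tifffile.imread(core.shg_image_ref).astype(np.float64)
        except Exception as e:  # unreadable -> flagged, not dropped
            excluded.append(replace_core(core, True, f"read_error: {e}"))
            continue
        frac = fx.foreground_fraction(img, ext_cfg)
        if frac < config.no_signal_foreground_fraction:
            excluded.append(
                replace_core(core, True, f"no_signal: foreground fraction {frac:.2e}")
            )
        else:
            retained.append(replace_core(core, False, None))
    return retained, excluded


def replace_core(core: TMACore, excluded: bool, reason: str | None) -> TMACore:
    out = TMACore(
        core_id=core.core_id,
        patient_id=core.patient_id,
        grade=core.grade,
        shg_image_ref=core.shg_image_ref,
        he_image_ref=core.he_image_ref,
        rois=core.rois,
        excluded=excluded,
        exclusion_reason=reason,
        true_transform=core.true_transform,
    )
    return out


def build_observation_table(
    cores: Sequence[TMACore],
    roi_metrics: Mapping[tuple[str, str], mx.ROIMetrics],
) -> list[ObservationRow]:
    """One ObservationRow per ROI of every retained core; alignment is missing
    where the minimum-fiber rule applied. Metrics must cover every ROI and
    (core_id, roi_id) keys must be unique."""
    rows: list[ObservationRow] = []
    seen: set[tuple[str, str]] = set()
    for core in cores:
        g = 1 if core.grade == "grade4" else 0
        for roi in core.rois:
            key = (core.core_id, roi.roi_id)
            if key in seen:
                raise ValueError(f"duplicate roi_id {roi.roi_id!r} in core {core.core_id!r}")
            seen.add(key)
            if key not in roi_metrics:
                raise ValueError(f"missing metrics for ROI {key}")
            m = roi_metrics[key]
            rows.append(
                ObservationRow(
                    patient_id=core.patient_id,
                    g=g,
                    core_id=core.core_id,
                    roi_id=roi.roi_id,
                    density=m.n_valid_fibers,
                    alignment=m.alignment_R,
                    intensity_fraction=m.intensity_fraction,
                )
            )
    return rows


def observations_to_frame(rows: Sequence[ObservationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "g": [r.g for r in rows],
            "core_id": [r.core_id for r in rows],
            "roi_id": [r.roi_id for r in rows],
            "density": [r.density for r in rows],
            "alignment": [np.nan if r.alignment is None else r.alignment for r in rows],
            "intensity_fraction": [r.intensity_fraction for r in rows],
        }
    )


@dataclass
class PipelineResult:
    observations: pd.DataFrame
    comparison: "st.GradeComparison | None"
    retained: list[TMACore]
    excluded: list[TMACore]
    failures: list[tuple[str, str]]
    transforms: dict
    exit_code: int


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """End-to-end run: load manifest -> exclude no-signal cores -> register
    H&E to SHG per core -> map and crop ROIs -> extract and filter fibers ->
    per-ROI metrics -> observation table -> mixed-model grade comparison.

    Per-core failures are recorded and the remaining cores processed; a
    nonzero exit code signals any failure or a skipped model. Writes
    ``roi_metrics.csv``, ``model_summary.json``, ``boxplot_summary.csv``,
    ``transforms.json`` and ``exclusions.log`` into ``out_dir``.
    """
    from .model import load_manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cores, meta = load_manifest(manifest_path)
    retained, excluded = exclude_no_signal_cores(cores, config)

    ext_cfg = _extraction_config(config)
    metrics: dict[tuple[str, str], mx.ROIMetrics] = {}
    failures: list[tuple[str, str]] = []
    transforms: dict[str, dict] = {}
    ok_cores: list[TMACore] = []

    for core in retained:
        try:
            shg = tifffile.imread(core.shg_image_ref).astype(np.float64)
            if core.he_image_ref is not None:
                he = tifffile.imread(core.he_image_ref)
                reg = rg.register_he_to_shg(
                    shg,
                    he,
                    config.shg_pixel_size_um,
                    config.he_pixel_size_um,
                    model=config.registration_model,
                    seed=config.seed,
                    settings=rg.IntensityRegistrationSettings(
                        n_levels=config.registration_levels,
                        finest_factor=config.registration_finest_factor,
                        full_refinement=False,
                    ),
                )
                if reg.converged:
                    t = reg.transform
                else:
                    # failed registration: fall back to the calibrated
                    # pixel-size rescaling rather than a wrong estimate
                    ratio = config.he_pixel_size_um / config.shg_pixel_size_um
                    t = AffineTransform2D.scaling(ratio)
                transforms[core.core_id] = {
                    "matrix": t.matrix.ravel().tolist(),
                    "model": t.model,
                    "metric": reg.final_metric,
                    "converged": reg.converged,
                    "fallback_scale_only": not reg.converged,
                }
            else:
                ratio = config.he_pixel_size_um / config.shg_pixel_size_um
                t = AffineTransform2D.scaling(ratio)
            core_metrics: dict[tuple[str, str], mx.ROIMetrics] = {}
            for roi in core.rois:
                roi_shg = (
                    rg.transform_roi(
                        roi,
                        t,
                        scales=(config.he_pixel_size_um, config.shg_pixel_size_um),
                        shg_shape=shg.shape,
                    )
                    if roi.space == "he"
                    else roi
                )
                img = crop_roi(shg, roi_shg)
                pre = fx.preprocess(img, ext_cfg)
                mask = fx.fiber_mask(pre, ext_cfg)
                traces = fx.extract_fibers(pre, ext_cfg)
                valid = fx.filter_valid_fibers(traces, ext_cfg)
                core_metrics[(core.core_id, roi.roi_id)] = mx.ROIMetrics(
                    n_valid_fibers=mx.collagen_density(valid),
                    alignment_R=mx.alignment_coefficient(
                        [f.orientation_deg for f in valid], config.n_min_alignment
                    ),
                    intensity_fraction=mx.intensity_density(img, mask),
                )
                if keep_intermediates:
                    tifffile.imwrite(
                        out_dir / f"{core.core_id}_{roi.roi_id}_shg.tif",
                        img.astype(np.float32),
                    )
            metrics.update(core_metrics)
            ok_cores.append(core)
        except Exception as e:
            logger.exception("core %s failed", core.core_id)
            failures.append((core.core_id, f"{type(e).__name__}: {e}"))

    rows = build_observation_table(ok_cores, metrics)
    obs = observations_to_frame(rows)
    obs = obs.sort_values(["core_id", "roi_id"]).reset_index(drop=True)
    obs.to_csv(out_dir / "roi_metrics.csv", index=False, float_format="%.6f")

    comparison = None
    comparison_error = None
    try:
        comparison = st.compare_grades(obs)
    except st.ModelInputError as e:
        comparison_error = str(e)

    with open(out_dir / "exclusions.log", "w") as fh:
        for core in excluded:
            fh.write(f"{core.core_id}\t{core.exclusion_reason}\n")
        for core_id, err in failures:
            fh.write(f"{core_id}\tstage_failure: {err}\n")

    with open(out_dir / "transforms.json", "w") as fh:
        json.dump(transforms, fh, indent=1)

    summary: dict = {
        "n_input_cores": len(cores),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "n_failures": len(failures),
    }
    if comparison is not None:
        summary.update(comparison.to_dict())
        box_rows = []
        for (outcome, grp), s in comparison.boxplots.items():
            box_rows.append({"outcome": outcome, "group": grp, **s.to_dict()})
        pd.DataFrame(box_rows).to_csv(out_dir / "boxplot_summary.csv", index=False)
    else:
        summary["model_error"] = comparison_error
    with open(out_dir / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)

    exit_code = 0
    if failures or comparison is None or (comparison is not None and comparison.skipped):
        exit_code = 1
    return PipelineResult(
        observations=obs,
        comparison=comparison,
        retained=retained,
        excluded=excluded,
        failures=failures,
        transforms=transforms,
        exit_code=exit_code,
    )
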