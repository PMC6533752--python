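"""H&E-to-SHG registration: color segmentation + intensity optimization.

H&E and SHG intensities are not directly comparable, so registration works
on a stain-density proxy: the H&E image is segmented by K-means in RGB space,
the tissue mask (everything but the near-white background cluster) gates an
inverted-brightness "stain density" image, and that proxy — resampled to the
SHG pixel grid — is registered to the Gaussian-smoothed SHG image by
minimizing the mean-squared difference of z-normalized intensities over a
multi-resolution pyramid (Powell search, phase-correlation translation init).
A least-squares landmark fit is available as the fallback for cores where the
intensity metric fails (e.g. very weak collagen signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import estimate_transform

from .model import ROIAnnotation
from .transforms import AffineTransform2D, SingularTransformError

__all__ = [
    "LandmarkPairSet",
    "RegistrationResult",
    "segment_he_kmeans",
    "register_intensity",
    "register_landmarks",
    "register_he_to_shg",
    "transform_roi",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LandmarkPairSet:
    """Corresponding (H&E point, SHG point) pairs, each (x, y)."""

    he_points: np.ndarray
    shg_points: np.ndarray

    def __post_init__(self) -> None:
        he = np.atleast_2d(np.asarray(self.he_points, float))
        shg = np.atleast_2d(np.asarray(self.shg_points, float))
        if he.shape != shg.shape or he.shape[1] != 2:
            raise ValueError("landmark arrays must both be (n, 2)")
        object.__setattr__(self, "he_points", he)
        object.__setattr__(self, "shg_points", shg)

    def __len__(self) -> int:
        return len(self.he_points)


@dataclass(frozen=True)
class RegistrationResult:
    transform: AffineTransform2D
    final_metric: float
    converged: bool
    metric_trace: tuple[float, ...] = ()
    model: str = "similarity"


# ---------------------------------------------------------------------------
# K-means color segmentation
# ---------------------------------------------------------------------------


def segment_he_kmeans(
    he: np.ndarray, k: int = 3, seed: int = 0, max_fit_px: int = 50_000
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster RGB pixels into ``k`` color groups and return the label image
    plus the tissue mask (all clusters except the one nearest white).

    Deterministic for a given seed (single k-means++ initialization; fitted on
    a seeded subsample for large images, then all pixels assigned). A
    degenerate near-single-color image yields an empty mask with a warning.
    """
    if he.size == 0:
        raise ValueError("empty image")
    if k < 2:
        raise ValueError("k must be >= 2")
    img = np.asarray(he, dtype=np.float64)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    h, w = img.shape[:2]
    flat = img.reshape(-1, 3)

    uniq = np.unique(flat, axis=0)
    if len(uniq) < k:
        warnings.warn("degenerate image: fewer distinct colors than clusters")
        labels = np.zeros((h, w), dtype=int)
        return labels, np.zeros((h, w), dtype=bool)

    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    if len(flat) > max_fit_px:
        idx = rng.choice(len(flat), size=max_fit_px, replace=False)
        fit_data = flat[idx]
    else:
        fit_data = flat
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    km.fit(fit_data)
    labels = km.predict(flat).reshape(h, w)

    white = np.array([255.0, 255.0, 255.0])
    dist_white = np.linalg.norm(km.cluster_centers_ - white, axis=1)
    background = int(np.argmin(dist_white))
    if dist_white.max() < 20.0:
        warnings.warn("all clusters near white: empty tissue mask")
        return labels, np.zeros((h, w), dtype=bool)
    tissue = labels != background
    return labels, tissue


def stain_density_proxy(
    he: np.ndarray,
    tissue_mask: np.ndarray,
    labels: np.ndarray | None = None,
    sigma: float = 1.5,
) -> np.ndarray:
    """Grayscale registration proxy: eosin stain density.

    Inverted brightness gated by the tissue mask, so eosin-dense (fiber-rich)
    bands score high and inter-fiber gaps low — the same spatial structure a
    smoothed SHG image shows. Hematoxylin nuclei are a confound (dark but
    collagen-free): when a ``labels`` image is given, pixels of the darkest
    cluster are replaced by the median tissue density before smoothing.
    """
    img = np.asarray(he, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    density = (255.0 - img) / 255.0
    density[~tissue_mask] = 0.0
    if labels is not None and tissue_mask.any():
        brightness = [
            img[labels == lab].mean() if np.any(labels == lab) else 255.0
            for lab in range(int(labels.max()) + 1)
        ]
        darkest = int(np.argmin(brightness))
        med = float(np.median(density[tissue_mask]))
        if brightness[darkest] < 0.7 * float(np.median(img[tissue_mask])):
            density[(labels == darkest) & tissue_mask] = med
    return ndi.gaussian_filter(density, sigma)


# ---------------------------------------------------------------------------
# intensity-based registration
# ---------------------------------------------------------------------------


def _warp(img: np.ndarray, t: AffineTransform2D, out_shape: tuple[int, int], cval=0.0) -> np.ndarray:
    """Resample ``img`` so that out(x) = img(t^-1 x) for (x, y) coordinates."""
    inv = t.inverse()
    # scipy affine_transform maps output (row, col) -> input via matrix/offset
    lin_xy = inv.linear
    off_xy = inv.offset
    matrix_rc = lin_xy[::-1, ::-1]
    offset_rc = off_xy[::-1]
    return ndi.affine_transform(
        img, matrix_rc, offset=offset_rc, output_shape=out_shape, order=1, cval=cval
    )


def _znorm(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd == 0:
        return img - img.mean()
    return (img - img.mean()) / sd


def _params_to_transform(
    params: np.ndarray, model: str, center: tuple[float, float], init: AffineTransform2D
) -> AffineTransform2D:
    if model == "translation":
        corr = AffineTransform2D.translation(params[0], params[1])
    elif model == "rigid":
        corr = AffineTransform2D.similarity(1.0, params[0], (params[1], params[2]), center)
    elif model == "similarity":
        corr = AffineTransform2D.similarity(
            float(np.exp(params[0])), params[1], (params[2], params[3]), center
        )
    elif model == "affine":
        da = params[:4].reshape(2, 2)
        m = np.eye(3)
        m[:2, :2] = np.eye(2) + da
        cx, cy = center
        c = np.array([cx, cy])
        m[:2, 2] = c - m[:2, :2] @ c + params[4:6]
        corr = AffineTransform2D(m, model="affine")
    else:
        raise ValueError(f"unknown model {model!r}")
    out = corr @ init
    return AffineTransform2D(out.matrix, model=model, meta=out.meta)


_N_PARAMS = {"translation": 2, "rigid": 3, "similarity": 4, "affine": 6}


@dataclass(frozen=True)
class IntensityRegistrationSettings:
    """Pyramid levels run coarsest-first at factors
    ``finest_factor * downscale**l`` for ``l = n_levels-1 .. 0``; a
    ``finest_factor`` above 1 trades subpixel precision for speed by never
    optimizing at full resolution."""

    n_levels: int = 3
    downscale: float = 2.0
    finest_factor: float = 1.0
    smooth_sigma: float = 2.0
    maxiter: int = 60
    min_overlap: float = 0.25
    # bounds on the correction away from the init: images arrive resampled
    # to a common calibrated pixel size, so residual scale/rotation are small
    max_log_scale: float = 0.2
    max_rotation_deg: float = 20.0
    max_translation_frac: float = 0.35
    # when False, fine pyramid levels re-optimize translation only (fast
    # whole-cohort mode); when True every level refines all parameters
    full_refinement: bool = True


def register_intensity(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str = "similarity",
    init: AffineTransform2D | None = None,
    settings: IntensityRegistrationSettings | None = None,
) -> RegistrationResult:
    """Estimate the transform (moving -> fixed coordinates) minimizing the MSE
    of z-normalized, Gaussian-smoothed intensities over a multi-resolution
    pyramid. Both images must share a pixel size. Non-convergence is flagged
    on the result, not raised.
    """
    if model not in _N_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    settings = settings or IntensityRegistrationSettings()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    # pad to a common shape (content stays anchored at the origin)
    H = max(fixed.shape[0], moving.shape[0])
    W = max(fixed.shape[1], moving.shape[1])
    f = np.zeros((H, W))
    f[: fixed.shape[0], : fixed.shape[1]] = fixed
    m = np.zeros((H, W))
    m[: moving.shape[0], : moving.shape[1]] = moving
    center = ((W - 1) / 2.0, (H - 1) / 2.0)

    init = init or AffineTransform2D.identity(model="affine")

    # pyramid, coarsest first
    levels = []
    for li in range(settings.n_levels - 1, -1, -1):
        factor = settings.finest_factor * settings.downscale**li
        if factor > 1:
            sigma_aa = 0.5 * factor
            fl = ndi.zoom(ndi.gaussian_filter(f, sigma_aa), 1.0 / factor, order=1)
            ml = ndi.zoom(ndi.gaussian_filter(m, sigma_aa), 1.0 / factor, order=1)
        else:
            fl, ml = f, m
        fl = _znorm(ndi.gaussian_filter(fl, settings.smooth_sigma))
        ml = _znorm(ndi.gaussian_filter(ml, settings.smooth_sigma))
        levels.append((factor, fl, ml))

    # translation init from phase correlation at the coarsest level
    factor0, fl0, ml0 = levels[0]
    init_is_identity = np.allclose(init.matrix, np.eye(3))
    params = np.zeros(_N_PARAMS[model])
    if init_is_identity:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shift, _, _ = phase_cross_correlation(fl0, ml0, upsample_factor=4)
        tx, ty = float(shift[1] * factor0), float(shift[0] * factor0)
        if model == "translation":
            params[:2] = (tx, ty)
        elif model == "rigid":
            params[1:3] = (tx, ty)
        elif model == "similarity":
            params[2:4] = (tx, ty)
        else:
            params[4:6] = (tx, ty)

    max_t = settings.max_translation_frac * max(H, W)

    def bound_penalty(p):
        """Quadratic wall outside the plausible correction range."""
        if model == "translation":
            ls, th, tx, ty = 0.0, 0.0, p[0], p[1]
        elif model == "rigid":
            ls, th, tx, ty = 0.0, p[0], p[1], p[2]
        elif model == "similarity":
            ls, th, tx, ty = p[0], p[1], p[2], p[3]
        else:
            ls = float(np.abs(p[:4]).max())
            th, tx, ty = 0.0, p[4], p[5]
        pen = 0.0
        for val, lim in ((ls, settings.max_log_scale), (th, settings.max_rotation_deg),
                         (tx, max_t), (ty, max_t)):
            excess = abs(val) - lim
            if excess > 0:
                pen += 1e4 * (1.0 + excess) ** 2
        return pen

    trace: list[float] = []
    ok = True
    for li, (factor, fl, ml) in enumerate(levels):
        scale_t = AffineTransform2D.scaling(1.0 / factor)
        # the finest levels only polish the coarse solution: few cycles
        if li == 0 or settings.full_refinement:
            level_maxiter = settings.maxiter
        else:
            level_maxiter = max(settings.maxiter // 10, 3)

        # overlap fraction from mapped corners on a coarse probe grid is
        # far cheaper than warping a support image every evaluation
        hh, ww = fl.shape
        gy, gx = np.mgrid[0 : hh : max(hh // 16, 1), 0 : ww : max(ww // 16, 1)]
        probe = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)

        def objective(p):
            pen = bound_penalty(p)
            if pen > 0:
                return pen
            t_full = _params_to_transform(p, model, center, init)
            t_lvl = scale_t @ t_full @ scale_t.inverse()
            src = t_lvl.inverse().apply(probe)
            inside = (
                (src[:, 0] >= 0) & (src[:, 0] < ml.shape[1])
                & (src[:, 1] >= 0) & (src[:, 1] < ml.shape[0])
            )
            frac = float(inside.mean())
            if frac < settings.min_overlap:
                return 1e6 * (settings.min_overlap - frac + 1.0)
            warped = _warp(ml, t_lvl, fl.shape, cval=0.0)
            return float(np.mean((fl - warped) ** 2))

        # angle parameters are in degrees; give Powell sensible initial steps
        direc = np.eye(len(params))
        step = {
            "translation": [2.0, 2.0],
            "rigid": [1.0, 2.0, 2.0],
            "similarity": [0.02, 1.0, 2.0, 2.0],
            "affine": [0.02] * 4 + [2.0, 2.0],
        }[model]
        direc *= np.asarray(step)
        refine_translation_only = (
            li > 0 and model != "translation" and not settings.full_refinement
        )
        if refine_translation_only:
            # fine levels refine translation only; scale/rotation are set
            # at the coarse level where the basin is widest
            fixed_head = params[:-2].copy()

            def objective2(t2):
                return objective(np.concatenate([fixed_head, t2]))

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(
                    objective2,
                    params[-2:],
                    method="Powell",
                    options={
                        "maxiter": level_maxiter,
                        "xtol": 1e-3,
                        "ftol": 1e-6,
                        "direc": 2.0 * np.eye(2),
                    },
                )
            params = np.concatenate([fixed_head, np.asarray(res.x, dtype=float)])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(
                    objective,
                    params,
                    method="Powell",
                    options={
                        "maxiter": level_maxiter,
                        "xtol": 1e-3,
                        "ftol": 1e-6,
                        "direc": direc,
                    },
                )
            params = np.asarray(res.x, dtype=float)
        trace.append(float(res.fun))
        ok = ok and bool(np.isfinite(res.fun))

    t_final = _params_to_transform(params, model, center, init)
    converged = ok and trace[-1] < 1e5
    return RegistrationResult(
        transform=AffineTransform2D(t_final.matrix, model=model, meta={"metric": trace[-1]}),
        final_metric=trace[-1],
        converged=converged,
        metric_trace=tuple(trace),
        model=model,
    )


# ---------------------------------------------------------------------------
# landmark fallback
# ---------------------------------------------------------------------------

_MIN_PAIRS = {"translation": 1, "rigid": 2, "similarity": 2, "affine": 3}
_SK_MODEL = {"rigid": "euclidean", "similarity": "similarity", "affine": "affine"}


def register_landmarks(pairs: LandmarkPairSet, model: str = "affine") -> AffineTransform2D:
    """Least-squares transform T minimizing sum ||T(p_he) - p_shg||^2.

    The residual RMS is stored in ``meta['residual_rms']``. Raises on too few
    or collinear points for the requested model.
    """
    if model not in _MIN_PAIRS:
        raise ValueError(f"unknown model {model!r}")
    n = len(pairs)
    if n < _MIN_PAIRS[model]:
        raise ValueError(f"model {model!r} needs >= {_MIN_PAIRS[model]} landmark pairs, got {n}")
    src, dst = pairs.he_points, pairs.shg_points
    if model == "affine":
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError("landmarks are collinear: affine fit is underdetermined")
    else:
        if model in ("rigid", "similarity") and len(np.unique(src, axis=0)) < 2:
            raise ValueError("landmarks are coincident: fit is underdetermined")
    if model == "translation":
        t = (dst - src).mean(axis=0)
        out = AffineTransform2D.translation(*t)
    elif model == "affine":
        # plain normal-equations solution (no point normalization)
        A = np.hstack([src, np.ones((n, 1))])
        coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
        out = AffineTransform2D(np.vstack([coef.T, [0.0, 0.0, 1.0]]), model="affine")
    else:
        sk = estimate_transform(_SK_MODEL[model], src, dst)
        params = np.asarray(sk.params, float)
        if not np.all(np.isfinite(params)):
            raise ValueError("landmark fit failed (degenerate geometry)")
        out = AffineTransform2D(params, model=model)
    resid = out.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(out.matrix, model=model, meta={"residual_rms": rms})


# ---------------------------------------------------------------------------
# whole-core registration and ROI mapping
# ---------------------------------------------------------------------------


def register_he_to_shg(
    shg: np.ndarray,
    he: np.ndarray,
    shg_pixel_size_um: float,
    he_pixel_size_um: float,
    model: str = "similarity",
    seed: int = 0,
    k: int = 3,
    shg_smooth_sigma: float = 2.0,
    mask_blur_sigma: float = 3.0,
    settings: IntensityRegistrationSettings | None = None,
) -> RegistrationResult:
    """Full-core registration: K-means tissue segmentation of the H&E image,
    stain-density proxy, resampling to the SHG grid, then intensity
    registration. Returns the H&E-pixel -> SHG-pixel transform.

    To make the two modalities comparable under a mean-squared-difference
    metric, both sides are reduced to blurred foreground masks (Otsu on the
    smoothed SHG; Otsu on the positive part of the upsampled stain-density
    proxy). Symmetric mask-vs-mask matching avoids the small scale bias that
    direct band-vs-ridge intensity matching introduces.
    """
    from skimage.filters import threshold_otsu

    labels, tissue = segment_he_kmeans(he, k=k, seed=seed)
    if not tissue.any():
        return RegistrationResult(
            transform=AffineTransform2D.identity(model=model),
            final_metric=float("inf"),
            converged=False,
            model=model,
        )
    proxy = stain_density_proxy(he, tissue, labels=labels)
    ratio = he_pixel_size_um / shg_pixel_size_um  # > 1: upsample
    scale_t = AffineTransform2D.scaling(ratio)
    proxy_up = _warp(proxy, scale_t, shg.shape, cval=0.0)
    shg_sm = ndi.gaussian_filter(np.asarray(shg, float), shg_smooth_sigma)
    positive = proxy_up[proxy_up > 1e-6]
    if positive.size == 0 or np.ptp(shg_sm) == 0:
        return RegistrationResult(
            transform=AffineTransform2D.identity(model=model),
            final_metric=float("inf"),
            converged=False,
            model=model,
        )
    fixed_mask = (shg_sm > threshold_otsu(shg_sm)).astype(float)
    moving_mask = (proxy_up > threshold_otsu(positive)).astype(float)
    fixed_blur = ndi.gaussian_filter(fixed_mask, mask_blur_sigma)
    moving_blur = ndi.gaussian_filter(moving_mask, mask_blur_sigma)
    settings = settings or IntensityRegistrationSettings()
    res = register_intensity(fixed_blur, moving_blur, model=model, settings=settings)
    # a correction that ran into its bounds is a failed registration, not an
    # estimate: flag it so the caller can fall back
    corr = res.transform
    converged = res.converged
    if (
        abs(float(np.log(max(corr.scale, 1e-9)))) > 0.9 * settings.max_log_scale
        or abs(corr.rotation_deg) > 0.9 * settings.max_rotation_deg
    ):
        converged = False
    full = corr @ scale_t
    return RegistrationResult(
        transform=AffineTransform2D(full.matrix, model=model, meta=corr.meta),
        final_metric=res.final_metric,
        converged=converged,
        metric_trace=res.metric_trace,
        model=model,
    )


def transform_roi(
    roi: ROIAnnotation,
    t: AffineTransform2D,
    scales: tuple[float, float] | None = None,
    shg_shape: tuple[int, int] | None = None,
) -> ROIAnnotation:
    """Map an H&E-space ROI rectangle into SHG pixel coordinates.

    The four corners are mapped and the axis-aligned bounding rectangle,
    rounded outward to integers, is returned (so a round trip through the
    inverse transform always contains the original). When ``scales`` =
    (he_um, shg_um) is given, the center shift relative to the pure
    pixel-size rescaling is recorded in ``meta['shift_px']``.
    """
    if not t.is_invertible:
        raise SingularTransformError("ROI transform is singular")
    corners = np.array(
        [
            [roi.x0, roi.y0],
            [roi.x1, roi.y0],
            [roi.x0, roi.y1],
            [roi.x1, roi.y1],
        ],
        dtype=float,
    )
    mapped = t.apply(corners)
    x0, y0 = np.floor(mapped.min(axis=0))
    x1, y1 = np.ceil(mapped.max(axis=0))
    if shg_shape is not None:
        h, w = shg_shape
        if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
            raise RegistrationError(
                f"ROI {roi.roi_id} maps entirely outside the SHG image"
            )
    meta = {}
    if scales is not None:
        he_um, shg_um = scales
        ratio = he_um / shg_um
        center = corners.mean(axis=0)
        meta["shift_px"] = float(np.linalg.norm(t.apply(center)[0] - ratio * center))
    return ROIAnnotation(
        roi_id=roi.roi_id,
        x0=int(x0),
        y0=int(y0),
        x1=int(x1),
        y1=int(y1),
        space="shg",
        meta=meta,
    )
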