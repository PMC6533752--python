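"""Grade-group comparison with random-intercept linear mixed models.

Each collagen feature y_ij (ROI j of patient i) is modelled as

    y_ij = beta0 + beta1 * g_i + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

where g_i is 1 for the high-grade group. The random intercept b_i absorbs
the within-patient correlation of repeated ROI measurements. Estimation is
REML (statsmodels MixedLM); the two-sided test and 95% CI for beta1 use a
t reference distribution with the between-within degrees of freedom
``n_obs - n_patients - 1``. ROIs with a missing outcome (alignment below the
minimum-fiber rule) are dropped listwise for that outcome only, so the
density and alignment fits generally use different sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixedModelFit",
    "BoxplotSummary",
    "fit_random_intercept_model",
    "summarize_boxplot",
    "compare_grades",
    "simulate_mixed_cohort",
]


@dataclass(frozen=True)
class MixedModelFit:
    beta0: float
    beta1: float
    ci95: tuple[float, float]
    p_value: float
    sigma_b: float
    sigma_e: float
    n_obs: int
    n_patients: int
    converged: bool
    method: str = "reml"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(self.ci95)
        return d


@dataclass(frozen=True)
class BoxplotSummary:
    """Default-boxplot summary: median, quartiles (linear interpolation),
    whiskers at the most extreme points within 1.5*IQR of the quartiles,
    and the flagged outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outliers"] = list(self.outliers)
        return d


class ModelInputError(ValueError):
    """Raised when the observation table cannot support the grade contrast."""


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    rows = []
    for r in table:
        rows.append(
            {
                "patient_id": r.patient_id,
                "g": r.g,
                "roi_id": r.roi_id,
                "density": r.density,
                "alignment": np.nan if r.alignment is None else r.alignment,
                "intensity_fraction": r.intensity_fraction,
            }
        )
    return pd.DataFrame(rows)


def fit_random_intercept_model(table, outcome: str = "density") -> MixedModelFit:
    """REML fit of the random-intercept model for one outcome.

    ``table`` is a DataFrame (or iterable of observation rows) with columns
    ``patient_id``, ``g`` (0/1 group indicator) and the outcome column.
    Rows with a missing outcome are dropped. Requires at least two patients
    in each group. A noiseless degenerate table (every observation equal to
    its group constant) is fitted exactly with zero variance components.
    """
    df = _as_frame(table)
    if outcome not in df.columns:
        raise ModelInputError(f"outcome column {outcome!r} not in table")
    df = df.dropna(subset=[outcome])
    df = df.sort_values(["patient_id"]).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    g = df["g"].to_numpy(dtype=float)
    patients = df["patient_id"].to_numpy()
    for grp in (0, 1):
        if len(np.unique(patients[g == grp])) < 2:
            raise ModelInputError(
                f"need >=2 patients in group {grp} for the grade contrast "
                f"(outcome {outcome!r})"
            )
    n_obs = len(y)
    n_pat = len(np.unique(patients))
    dfree = max(n_obs - n_pat - 1, 1)

    beta0_ols = float(y[g == 0].mean())
    beta1_ols = float(y[g == 1].mean() - beta0_ols)
    resid = y - np.where(g == 1, beta0_ols + beta1_ols, beta0_ols)
    scale_ref = max(float(np.mean(y**2)), 1.0)
    if float(np.mean(resid**2)) <= 1e-12 * scale_ref:
        # exact fit: no residual variation at all
        p = 1.0 if beta1_ols == 0.0 else float(np.finfo(float).tiny)
        return MixedModelFit(
            beta0=beta0_ols,
            beta1=beta1_ols,
            ci95=(beta1_ols, beta1_ols),
            p_value=p,
            sigma_b=0.0,
            sigma_e=0.0,
            n_obs=n_obs,
            n_patients=n_pat,
            converged=True,
        )

    from statsmodels.regression.mixed_linear_model import MixedLM

    exog = np.column_stack([np.ones_like(g), g])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, exog, groups=patients)
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception:
            res = None
            converged = False
    if res is None or not np.all(np.isfinite(res.params[:2])):
        # fall back to OLS point estimates, flagged as non-converged
        se = float(np.sqrt(np.mean(resid**2) / max(n_obs - 2, 1)) *
                   np.sqrt(1.0 / max((g == 0).sum(), 1) + 1.0 / max((g == 1).sum(), 1)))
        tcrit = float(sps.t.ppf(0.975, dfree))
        tval = beta1_ols / se if se > 0 else np.inf
        return MixedModelFit(
            beta0=beta0_ols,
            beta1=beta1_ols,
            ci95=(beta1_ols - tcrit * se, beta1_ols + tcrit * se),
            p_value=float(2 * sps.t.sf(abs(tval), dfree)),
            sigma_b=float("nan"),
            sigma_e=float("nan"),
            n_obs=n_obs,
            n_patients=n_pat,
            converged=False,
        )

    beta0, beta1 = float(res.params[0]), float(res.params[1])
    se1 = float(res.bse[1])
    sigma_b = float(np.sqrt(max(float(np.asarray(res.cov_re)[0, 0]), 0.0)))
    sigma_e = float(np.sqrt(max(float(res.scale), 0.0)))
    tcrit = float(sps.t.ppf(0.975, dfree))
    tval = beta1 / se1 if se1 > 0 else np.inf
    p = float(2 * sps.t.sf(abs(tval), dfree))
    p = max(p, float(np.finfo(float).tiny))
    return MixedModelFit(
        beta0=beta0,
        beta1=beta1,
        ci95=(beta1 - tcrit * se1, beta1 + tcrit * se1),
        p_value=p,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        n_obs=n_obs,
        n_patients=n_pat,
        converged=converged,
    )


def summarize_boxplot(values: Sequence[float] | np.ndarray) -> BoxplotSummary:
    """Boxplot bookkeeping: median, Q1/Q3 (linear-interpolation quantiles),
    whiskers at the most extreme data within 1.5*IQR, outliers beyond."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("summarize_boxplot requires a nonempty list")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(sorted(x[(x < lo_fence) | (x > hi_fence)].tolist()))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(x.size),
    )


@dataclass(frozen=True)
class GradeComparison:
    fits: dict
    boxplots: dict
    counts: dict
    skipped: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return len(self.skipped) == 0

    def to_dict(self) -> dict:
        return {
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
            "boxplots": {
                f"{outcome}/{grp}": s.to_dict() for (outcome, grp), s in self.boxplots.items()
            },
            "counts": self.counts,
            "skipped": list(self.skipped),
        }


def compare_grades(table, outcomes: Iterable[str] = ("density", "alignment")) -> GradeComparison:
    """Fit the random-intercept model per outcome and summarize both groups.

    Outcomes with no usable rows (or too few patients) are recorded under
    ``skipped`` rather than raising, so a partial report is still produced.
    """
    df = _as_frame(table)
    fits: dict = {}
    boxes: dict = {}
    counts: dict = {}
    skipped: list[str] = []
    for outcome in outcomes:
        sub = df.dropna(subset=[outcome]) if outcome in df.columns else df.iloc[0:0]
        if outcome not in df.columns or sub.empty:
            skipped.append(outcome)
            continue
        try:
            fits[outcome] = fit_random_intercept_model(df, outcome)
        except ModelInputError:
            skipped.append(outcome)
            continue
        for grp in (0, 1):
            vals = sub.loc[sub["g"] == grp, outcome].to_numpy(dtype=float)
            boxes[(outcome, grp)] = summarize_boxplot(vals)
            counts[f"{outcome}/group{grp}"] = {
                "n_obs": int(len(vals)),
                "n_patients": int(sub.loc[sub["g"] == grp, "patient_id"].nunique()),
            }
    return GradeComparison(fits=fits, boxplots=boxes, counts=counts, skipped=tuple(skipped))


def simulate_mixed_cohort(
    n_per_group: tuple[int, int],
    rois_per_patient: int,
    beta0: float,
    beta1: float,
    sigma_b: float,
    sigma_e: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate an observation table directly from the random-intercept model
    (no images) — the Monte-Carlo harness for calibration checks."""
    rows = []
    pid = 0
    for grp, n in zip((0, 1), n_per_group):
        for _ in range(n):
            b = rng.normal(0.0, sigma_b)
            mu = beta0 + beta1 * grp + b
            for j in range(rois_per_patient):
                rows.append(
                    {
                        "patient_id": f"p{pid:04d}",
                        "g": grp,
                        "roi_id": f"r{j}",
                        "density": mu + rng.normal(0.0, sigma_e),
                    }
                )
            pid += 1
    return pd.DataFrame(rows)
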