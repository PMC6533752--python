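# fibergrade

Quantification of fibrillar collagen organization in second-harmonic
generation (SHG) images of tissue-microarray (TMA) cores, and comparison of
tumor-grade groups on the resulting per-ROI features. The package is aimed
at quantitative-pathology work where collagen density and alignment are
candidate stromal biomarkers — e.g. distinguishing low- from high-grade
renal cell carcinoma — and at method developers who need a fully
ground-truthed synthetic benchmark for fiber-level image analysis.

## What it computes

For each annotated region of interest (ROI, 400×400 H&E pixels = 202×202 µm
at full scale):

- **Collagen density** `n`: the number of *valid* fibers — individual fiber
  traces longer than 5.3 µm (30 SHG pixels) — extracted from the registered
  SHG crop by a FIRE-style algorithm (binarize → Euclidean distance
  transform → ridge tracing from EDT maxima → merge/link → per-fiber
  centerline, length, orientation, width).
- **Collagen alignment** `R`: the mean resultant length of the doubled
  axial orientations,

      R = (1/n) · √[(Σᵢ cos 2θᵢ)² + (Σᵢ sin 2θᵢ)²],   θᵢ ∈ [0°, 180°),

  which is 1 for parallel fibers and 0 for a mesh with no preferred axis.
  ROIs with fewer than 20 valid fibers report a missing `R`.
- **Intensity fraction**: foreground pixel fraction of the binarized ROI, a
  cross-check carrying the same density information as the fiber count.

Grade groups are compared per outcome with a random-intercept linear mixed
model, y_ij = β₀ + β₁·g_i + b_i + ε_ij with b_i ~ N(0, σ_b²) absorbing the
within-patient correlation of repeated ROIs (REML, two-sided t test on β₁
with between-within degrees of freedom, 95% Wald CI).

Because the upstream steps of such studies start from H&E annotations, the
package includes H&E→SHG registration (K-means tissue segmentation, a
stain-density proxy, multi-resolution intensity optimization, and a
least-squares landmark fallback), tile stitching, no-signal core exclusion,
and a synthetic-cohort generator whose fiber populations, transforms and
group effects are known exactly.

## Worked example

Generate a small two-group synthetic cohort and run the full pipeline:

```python
import tempfile
from fibergrade.synthetic import paper_like_small_spec, generate_cohort
from fibergrade.model import PipelineConfig
from fibergrade.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    spec = paper_like_small_spec(seed=2, n_per_group=(5, 5))
    generate_cohort(spec, tmp)                      # SHG+H&E TIFFs, cores.json, truth CSVs
    result = run_pipeline(PipelineConfig(), f"{tmp}/cores.json", f"{tmp}/out")
    for outcome, fit in result.comparison.fits.items():
        print(f"{outcome}: beta1={fit.beta1:.3f} "
              f"CI=({fit.ci95[0]:.3f}, {fit.ci95[1]:.3f}) p={fit.p_value:.2g}")
```

Output (printed by the code above):

```
density: beta1=34.867 CI=(24.519, 45.215) p=1e-06
alignment: beta1=0.272 CI=(0.163, 0.380) p=4.7e-05
```

`beta1` is the fitted grade-4 minus grade-1 difference: the high-grade-like
group has on average ~35 more valid fibers per ROI, and an alignment
coefficient higher by ~0.27 in this particular 5+5-patient draw (small
cohorts scatter widely around the scenario's planted contrast of ~0.09);
the CIs and p-values come from the random-intercept model, so they respect
that the 3 ROIs of a patient are correlated. The cohort-scale run in
`tests/test_acceptance.py`, at the analyzed-cohort sizes of 70 and 51
patients, recovers both contrasts positive at p < 0.001.

The same steps are available from a shell:

```
fibergrade synth --scenario paper-cohort --seed 1 --out cohort/
fibergrade run --manifest cohort/cores.json --out results/
fibergrade stats --metrics results/roi_metrics.csv --out results/
```

`run` writes `roi_metrics.csv` (one row per ROI), `model_summary.json`
(per-outcome β₀, β₁, CI, p, variance components, counts),
`boxplot_summary.csv`, `transforms.json` and `exclusions.log`.

## Layout

- `fibergrade.synthetic` — ground-truthed SHG/H&E core and cohort generator
- `fibergrade.model` — cores, ROIs, observations, configuration, manifest IO
- `fibergrade.pipeline` — stitching, cropping, exclusion, orchestration
- `fibergrade.registration` — K-means segmentation, intensity/landmark registration, ROI mapping
- `fibergrade.fibers` — preprocessing, binarization, ridge-tracing fiber extraction
- `fibergrade.metrics` — density, axial alignment coefficient, intensity fraction
- `fibergrade.stats` — mixed models, boxplot summaries, grade comparison
- `fibergrade.evaluation` — matching extracted fibers to ground truth

`docs/methods.md` documents the model assumptions, parameter defaults,
numerical choices and known limitations.
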