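# Methods

`fibergrade` quantifies fibrillar collagen in second-harmonic-generation
(SHG) images of tissue-microarray (TMA) cores and compares tumor-grade
groups on two per-ROI features: **collagen density** (the number of valid
fibers in a region of interest) and **collagen alignment** (the mean
resultant length of the fibers' axial orientations). Because each patient
contributes several ROIs, group comparison uses a linear mixed model with a
per-patient random intercept. A synthetic-data module generates SHG/H&E
core pairs with exactly known fiber populations, so every stage — H&E-to-SHG
registration, fiber extraction, the circular statistic, the mixed model — is
validated against ground truth rather than against another tool's output.

## Coordinate and unit conventions

Images are row-major with the origin at the top-left pixel; points are
`(x, y)` with `x` the column. Rectangles are 0-based half-open. SHG images
have a nominal pixel size of 0.1767 µm (so the 30-px fiber-length cutoff is
5.3 µm), bright-field H&E images 0.505 µm (so a 400-px ROI spans 202 µm).
Fiber orientations are *axial*: angles in `[0°, 180°)`, measured from the
+x axis toward +y (image "down"), with θ and θ+180° identified.

## Synthetic cores

Fibers are straight segments: a Poisson count with mean `fiber_count_mean`,
axial orientations from the doubled-angle von Mises construction
(φ ~ vM(2µ, κ), θ = φ/2 mod 180°), lognormal lengths in µm, uniform
midpoints, clipped to the image. Straightness matches what the downstream
statistic consumes — one orientation per fiber; curvature would not change
any quantity the pipeline measures. The doubled-angle construction is chosen
because it gives the closed-form expectation E[R] = I₁(κ)/I₀(κ) for the
alignment coefficient, which serves as an independent oracle in the tests.

Rendering splats each centerline into a float canvas, convolves with a
Gaussian of FWHM `fiber_width_um` (default 1.0 µm) plus a 0.4 µm-σ PSF,
scales to a peak fiber intensity of 600 counts over a background of 50, and
adds Poisson shot noise and Gaussian read noise (σ = 5). The paired
pseudo-H&E image paints the tissue footprint (core disk plus a ±1.2σ band
around each fiber) in two eosin pinks with a sparse hematoxylin nuclei
speckle over white, resamples to the H&E pixel size, and warps by a per-core
similarity "offset" that the pipeline never sees; the true H&E→SHG transform
is recorded in the ground-truth manifest. Blank cores (no tissue) emulate
cores without SHG signal.

Per-core randomness derives from `default_rng([seed, group, core_index])`,
so cohorts are reproducible core-by-core and different master seeds give
disjoint fiber populations.

### What the generator does and does not emulate

It reproduces the features the pipeline's contracts depend on: two cohorts
differing in fiber density and orientation concentration, within-patient
correlation (a per-core normal shift of the density mean; a per-core
lognormal jitter of κ), pixel-scale geometry, signal-dependent noise, an
unknown H&E offset, and no-signal cores. It does *not* emulate fiber
curvature or branching, stain variability, uneven illumination, tissue
folds, or scanner compression artifacts — so green tests demonstrate
correctness of the algorithms under the stated model, not robustness to
every property of real slides.

### Scenario calibration and problem sizes

The named `paper-cohort` scenario encodes the study bookkeeping: 75
annotated grade-1 cores (5 blank) with 3 ROIs each and 55 grade-4 cores
(4 blank) whose 51 retained cores carry 152 ROIs (one core with 2, fifty
with 3). Cores are rendered as 1000×1000-px SHG fields with 210-px
H&E-scale ROIs (600 SHG px = 106 µm): the examples and tests run at this
reduced field size, keeping the pixel scales and the 30-px validity
threshold exact while holding rendering and extraction costs at desk
scale. At this ROI size the
group means of per-ROI valid-fiber counts are set to 40 (grade-1-like) vs
110 (grade-4-like): a large positive density contrast in the direction of
the real cohorts, with both groups inside regimes where individual fibers
remain resolvable at this field size (at intermediate densities the
extractor's count response is noisier; at full scale the same areal
densities are unproblematic). Scenario fibers average 12 µm, which keeps
the denser group's fiber-area coverage near 10% — once coverage grows much
past that, crossing-fiber artifacts dominate the extracted orientations and
any individual-fiber method loses the alignment signal. Orientation
concentrations are κ = 1.0 vs 1.4. The κ gap is calibrated on the
*measured* scale: published alignment contrasts are computed from
extracted fibers, and extraction attenuates the latent Bessel-ratio gap
(here 0.124) by roughly a quarter in the denser group, so the
pipeline-measured contrast lands near 0.09 — the scale of the published
value. The between-patient density SD is 10 fibers/ROI and the κ jitter SD
is 0.25 on the log scale; the latter puts the between-patient scatter of
per-patient alignment near 0.1, consistent with the scatter implied by the
published confidence-interval width, which is why directional runs use the
real cohort's sample sizes (70 and 51 patients) — at much smaller cohorts
the alignment contrast is genuinely under-powered.

## Registration

ROIs are annotated on H&E and must be mapped to SHG pixels. The H&E image
is clustered in RGB by K-means (k = 3: background, eosin, hematoxylin;
seeded k-means++ with one initialization, fitted on a seeded subsample for
large images). The tissue mask is everything outside the cluster nearest
white. A *stain-density proxy* — inverted brightness gated by the tissue
mask, with the darkest (hematoxylin) cluster replaced by the median tissue
density, since nuclei are collagen-free — is resampled to the SHG grid.
Both modalities are then reduced to blurred foreground masks (Otsu on the
smoothed SHG; Otsu on the positive proxy) and registered by minimizing the
mean-squared difference of z-normalized images over a coarse-to-fine
pyramid (Powell search; translation initialized by phase correlation).
Mask-vs-mask matching is used because direct band-vs-ridge intensity
matching leaves a small (~0.5%) scale bias from the different cross-section
shapes of the two modalities.

The default transform family is similarity (rotation, isotropic scale,
translation): TMA cores undergo no shear in principle. A least-squares
landmark fit (`register_landmarks`) is available as the fallback for cores
whose collagen signal is too weak for the intensity metric; for the affine
family it solves the plain normal equations, for rigid/similarity the
Umeyama closed form. The optimizer bounds the correction away from its
initialization (|log scale| ≤ 0.2, rotation ≤ 20°, translation ≤ 35% of the
image): both images arrive resampled to calibrated pixel sizes, so a large
correction is always a failed registration, and a correction at its bounds
is flagged non-converged — `run_pipeline` then falls back to the pure
pixel-size rescaling rather than using a wrong estimate. Within
`run_pipeline`, registration runs at half resolution (pyramid factors 4
and 2) with a translation-only polish at the fine level — on synthetic
pairs this maps ROI centers within a few SHG px (~1 µm), ample against the
600-px ROI, at a fraction of the full-resolution cost; the full-precision
setting recovers known similarity transforms within 1 px and 1°.

Mapped ROIs are snapped to the axis-aligned bounding rectangle of the
transformed corners, rounded outward (a round trip through the inverse can
therefore only grow a rectangle, never shrink it), and the center shift
relative to pure pixel-size rescaling is recorded.

## Fiber extraction

The extractor implements the distance-transform ridge-tracing scheme of
FIRE-style fiber tools:

1. **Band-pass preprocessing** — difference of Gaussians at 0.5× and 4× the
   fiber width. This replaces curvelet denoising; the contract downstream
   needs is ridge-preserving background suppression, and the swap is
   config-visible.
2. **Binarization** — a three-stage rule. A *presence gate* declares the
   field empty when fewer than 0.1% of pixels exceed a robust noise floor
   (median + 4 MAD-σ of the sub-median half; the sub-median restriction
   resists inflation by bright fibers). Otherwise the threshold is
   max(Otsu, floor); if that keeps under 5% of the field — the signature of
   a dense fibrous field whose band-pass undershoot has inflated the MAD —
   plain Otsu is used instead. The same presence measure operationalizes
   the cohort-level "no SHG signal" exclusion (default cutoff 0.1%
   foreground), replacing the original study's manual judgment with an
   explicit criterion; on synthetic blanks it reads ≲0.02%, on the
   sparsest fibrous cores ≳0.3%.
3. **Nucleation** — local maxima of the Euclidean distance transform above
   r_min = 1.5 px.
4. **Tracing** — from each seed, bidirectional walks to the highest-EDT
   foreground pixel in an annulus of radius 2 px, constrained to a 30° turn
   per step and to ridge pixels with EDT ≥ 1 px (so walks halt at the thin
   blur bridges between adjacent fibers instead of crossing them). Ties
   break to the lowest (row, col). Seeds already inside the claimed band of
   an accepted trace are skipped; since seeds are visited in descending EDT
   order, ridge-center traces are claimed first.
5. **Merging and linking** — a trace is a duplicate when ≥50% of its points
   lie within 1.5 px of an already-kept trace (proximity rather than exact
   point sharing, because independently seeded walks along one ridge land
   on alternating pixel phases). Fragments whose facing endpoints are
   within 4 px, with end tangents and joining chord collinear within 20°,
   are concatenated.
6. **Emission** — arc length × pixel size (µm); orientation as the
   principal axis of the centerline point cloud (robust to tracing
   direction and mild curvature; the end-to-end angle is available via
   config); mean width as twice the mean EDT along the centerline.

Validity filtering keeps fibers strictly longer than 5.3 µm (30 px),
matching the published cutoff. On 20 synthetic fields of ≤50 non-overlapping
fibers the tracer attains pooled precision ≈0.95, recall ≈0.93, and ≈3%
median length error; in crowded fields it undercounts (as any
individual-fiber method must once fibers overlap heavily), which compresses
but does not reorder group contrasts.

## ROI metrics

Density is the raw valid-fiber count (constant ROI area makes counts and
areal densities proportional). Alignment is
R = |Σ exp(2iθ_j)| / n on doubled angles; doubling is the standard axial
treatment and makes R = 0 for an even mix of perpendicular fibers (a
"mesh") and 1 for parallel fibers. ROIs with fewer than 20 valid fibers get
a *missing* alignment — never imputed — and drop out of the alignment model
only, so the two outcomes use different sample sizes. The per-ROI dropping
(rather than per-core) is the default; a config switch allows per-core
exclusion. The intensity cross-check is the foreground pixel fraction of
the binarized ROI.

## Group statistics

For each outcome y_ij (ROI j of patient i):

    y_ij = β₀ + β₁·g_i + b_i + ε_ij,   b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²)

with g_i = 1 for grade 4. Estimation is REML via statsmodels' `MixedLM`
(config-switchable to ML). The two-sided test and the 95% CI for β₁ use a
t reference with the between-within degrees of freedom
`n_obs − n_patients − 1`. Two degenerate regimes are handled explicitly:
a noiseless table (all residuals zero) returns the exact group-difference
fit with zero variance components, and a non-convergent REML fit falls back
to OLS point estimates flagged `converged=False`. With one observation per
patient σ_b and σ_e are confounded; their squares then sum to the OLS
residual variance. p-values are floored at the smallest positive float so
the reported value stays in (0, 1]. No multiple-testing correction is
applied across the two outcomes (both are reported at α = 0.05).

Calibration, measured by the package's own Monte-Carlo harness
(`simulate_mixed_cohort`, 30+30 patients × 3 ROIs): type-I error within
[0.03, 0.08] over 500 null replicates and ≥93% CI coverage of a planted β₁
over 400 replicates.

Boxplot summaries report the median, linear-interpolation quartiles,
whiskers at the most extreme points within 1.5×IQR of the quartiles, and
the points beyond as outliers.

## Numerical and degenerate-input choices

- Otsu on a constant image is undefined: empty foreground with a warning.
- Orientations outside [0, 180) are normalized modulo 180 with a warning
  (doubling makes this a no-op for R).
- K-means on a (near-)single-color image returns an empty tissue mask with
  a warning; whole-core registration then reports `converged=False` instead
  of raising.
- Unreadable core images are excluded with an explicit reason; a stage
  failure on one core never aborts the cohort run, and any failure turns
  the pipeline exit code nonzero.
- Stitching resolves overlapping tile pixels by the mean of contributors.
- All randomness flows from explicit integer seeds; reruns are
  byte-identical.

## Known limitations

- Extraction counts saturate in heavily crowded fields; density contrasts
  measured there are attenuated relative to truth.
- The registration similarity metric assumes eosin density and SHG fiber
  density are spatially correlated, which holds for the generator and for
  collagen-rich stroma but can fail for tissues where eosin stains
  non-collagenous structures heavily; the landmark fallback covers such
  cores.
- The intensity pipeline estimates at half resolution inside `run_pipeline`
  (ROI mapping errors up to a few px, ~1 µm); use the full-precision
  settings where subpixel registration matters.
- Branch points are not split into separate traces; a branched structure
  is traced as one fiber along its highest-ridge path.
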