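# Methods

## Overview

`bonetex` estimates DXA reference values (L1 BMD g/cm², L1 BMC g,
total-hip BMD g/cm², total-hip BMC g) from texture statistics of the
trabecular compartment of one axial CT cut, and compares the strength of
that texture–DXA coupling between a type-2-diabetes group and a
normative group. The pipeline is deterministic: every stage is a pure
function of (inputs, configuration, seed).

## Phantom and cohort simulator

Institutional CT/DXA pairs cannot be redistributed, so studies run on
synthetic cohorts with the statistical skeleton the analysis assumes.

**Per-subject latent state.** Each subject carries a latent areal BMD
drawn from N(bmd_mean, bmd_sd²), truncated to positive values. Defaults
`bmd_mean = 1.0 g/cm²`, `bmd_sd = 0.15 g/cm²` span the adult lumbar
range from osteoporotic (~0.7) to high-normal (~1.3).

**Phantom slice.** A square HU grid (default 96 px; a deliberately
scaled-down axial cut that still yields a ≈ 2.6-k-pixel ROI, ample for
stable histogram and GLCM statistics): background tissue at −100 HU, a
cortical ring at 800 HU (outer radius 0.8 × half-width, thickness 15 %
of the ring radius), and inside it a trabecular disc at
`trabecular_gain · latent_bmd + trabecular_offset_hu` (defaults
180 HU/(g/cm²), offset 0) plus spatially correlated Gaussian speckle:
unit-variance white noise smoothed with a Gaussian kernel
(`smoothing_scale = 1.5 px`), rescaled to `trabecular_noise_sd = 25 HU`.
The gain places a 1.0 g/cm² subject at 180 HU, mid-trabecular on
clinical CT; the speckle gives the GLCMs non-degenerate, tunable
statistics. With zero noise the interior is exactly the affine map,
which the tests exploit as a closed-form limit.

**DXA references.** Noiseless targets are proportional to the latent
BMD: L1 BMD = latent; hip BMD = 0.9 × latent; each site's BMC =
16 × site BMD (a minimal proportional BMD↔BMC link; the hip factor
keeps the four targets from being numerically identical). Measurement
noise is Gaussian with a group-specific SD on the BMD scale
(`dxa_noise_sd_t2d = 0.03`, `dxa_noise_sd_normal = 0.15` g/cm²),
multiplied by each target's magnitude factor so all four targets carry
the same signal-to-noise ratio.

**Why noise encodes the group difference.** The diabetic-vs-normal
correlation gap could arise from bone-quality texture changes or from
reference-measurement precision differences; published summary
statistics cannot distinguish these, so the simulator exposes both
knobs (texture noise and DXA noise) and encodes the default contrast
purely in DXA noise. The default SDs follow from
r ≈ σ_BMD / √(σ_BMD² + σ_noise²) plus the in-sample inflation of an
unregularized 46-parameter fit (≈ p/n): they place the diabetic group
near r ≈ 0.98 and the normative group near r ≈ 0.72–0.77 at the default
145/365 sample sizes.

**Demographics** (age, sex, BMI per group) are sampled from the
published per-group means and SDs; they are carried in the cohort table
for filtering but do not enter the generative model.

**Randomness.** One master seed spawns an independent stream per
subject (latent BMD, demographics, DXA noise, phantom speckle seed), so
any subject is regenerable in isolation and group counts can change
without reshuffling everyone else's draws... with the caveat that the
per-subject seeds are drawn sequentially from the master stream, so
inserting a subject shifts later draws; identical configs always give
identical cohorts.

**What passing tests do not show.** Phantoms are circularly symmetric,
stationary, and Gaussian; real vertebrae have oriented trabeculae,
marrow heterogeneity, partial-volume cortical bleed, beam hardening and
scanner-kernel effects. A pipeline validated here is validated as
*software* (correct formulas, correct wiring, correct statistics), not
as a clinical claim about real CT.

## ROI isolation

Pixels inside the HU window [0, 400] (above fat/soft tissue, below
cortical bone; the window is explicit configuration, not a constant)
are labeled with 8-connectivity; the largest component is kept; the
largest inscribed circle is found at the maximum of the Euclidean
distance transform and shrunk by `circle_margin_frac = 0.1` to stay
clear of the cortical boundary. A fixed-radius mode at the component
centroid exists for protocols that prefer a constant aperture. Slice
selection from a stack is a thin helper choosing the cut with maximal
in-window pixel count. Degenerate inputs fail loudly: no in-window
pixel → empty-ROI error; a component too small to hold a 1-px circle →
too-small-ROI error.

## Feature grid

All 45 features, in the frozen order (version tag `bonetex-45-v1`):

* **Histogram (5):** mean and SD in HU (population moments), skewness
  (third standardized moment), kurtosis (raw fourth standardized
  moment — 3 for a Gaussian, *not* excess), entropy −Σ h log₂ h over
  256 bins spanning the ROI min–max with 0·log 0 = 0. A constant ROI is
  legal: SD/skewness/kurtosis/entropy all 0.
* **GLCM (40):** for each direction (horizontal offset (0, 1), vertical
  (1, 0)) and each level count (16, 32, 64, 128), the ROI is min–max
  quantized (`bin = ⌊(v − min)/(max − min) · L⌋` clamped to L−1), pairs
  with both pixels inside the mask are counted, the reversed pair is
  added (symmetric), and counts are normalized to probabilities. The
  five statistics are contrast Σp(i,j)(i−j)², correlation
  Σp(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ) (0 when a marginal SD vanishes), energy
  Σp², homogeneity Σp/(1+|i−j|), and variance Σp(i,j)(i−μᵢ)².

Choices the grid definition leaves open, fixed here: offset distance 1
(nearest neighbor); symmetric normalized GLCMs (makes the
horizontal/vertical transpose duality exact and correlation
well-defined); per-ROI min–max quantization (shift- and
scale-invariant), with an optional fixed-HU-window mode for
cross-subject comparability — the pipeline records which mode produced
a feature table. Autocorrelation Σ i·j·p(i,j) is available as an extra
statistic but is not part of the canonical 45; variance holds the
fifth slot.

## Regression and the neural alternative

Features and target are z-scored over the fitting cohort (per-column
center/scale retained; zero-variance columns centered only and
flagged; min–max normalization available). The linear model's 46
weights are the minimum-norm least-squares solution via SVD
pseudoinverse — mathematically the normal-equation solution, but
rank-revealing, so exact collinearity degrades to a flagged minimum-norm
fit instead of a crash. The entire cohort is used with no train/test
split and no regularization; with n ≥ 47 enforced, the fit is
determined, and reported correlations are in-sample by design (their
p/n optimism is part of why the defaults land where they do; see the
simulator section). `sse = Σ(y−ŷ)²` and `mse = sse/n` are both always
reported, because a printed "MSE" may follow either convention.

The network is the fixed 45→8→8→2→1 ReLU architecture with a linear
output, trained by full-batch Adam (lr 10⁻², 5000 epochs) on the mean
squared error. Plain full-batch gradient descent — the most obvious
choice — stalls on dead-ReLU plateaus for a large fraction of
initializations at this width; Adam with 3 seeded He-initialization
restarts (best final loss kept) is the smallest deterministic procedure
that reliably reaches the linear-model optimum on linear targets. All
restart seeds derive from the one user seed. Non-finite loss raises a
training-failure error naming the learning rate.

## Inference and group comparison

For the linear fit, weight standard errors are
√(s² diag((XᵀX)⁻¹)) with s² the unbiased residual variance on n − 46
degrees of freedom; t = w/se; two-sided p from Student's t. The
"Constant" row is the bias w₀. If the design is rank-deficient the
columns involved in a dependency (detected by rank-invariant column
deletion) get NaN p, and the remaining columns are tested in the
restricted full-rank submodel. A univariate mode (each feature in its
own bias+feature regression, df = n − 2) is available and labeled in
the report; the default is the full 46-column fit.

Per target × group, features with p < α (default 0.05, raw) are
tabulated; the discordance list holds features significant in exactly
one group. No multiplicity correction is applied by default — under the
global null ≈ 45α ≈ 2.25 features per table are expected significant by
chance, which the calibration tests quantify — but Benjamini–Hochberg
adjustment is available and flagged in the report when used.

## Numerical and testing notes

* GLCM and statistic implementations are verified against exhaustive
  pair-enumeration and double-loop oracles to 1e−12, and against
  scikit-image on rectangular masks; the regression against generic
  least-squares solvers and statsmodels OLS inference to 1e−8/1e−10.
* Type-I error calibration is checked on simulated global-null cohorts
  (n = 120, 45 features): the pooled rejection rate at α = 0.05 must
  stay within the binomial 95 % band.
* Default problem sizes in tests and the acceptance script (96-px
  phantoms, 510-subject default cohort, 20-seed replication of the
  correlation contrast) were chosen so a full run completes in minutes
  on one core while leaving the statistical checks well-powered.
* Degenerate inputs have defined behavior throughout: constant ROIs,
  zero-noise phantoms, collinear features, zero-variance predictions
  (correlation undefined → explicit error), underdetermined cohorts
  (n < 47 → explicit error naming the requirement).

## Known limitations

* 2-D, single-slice analysis; no vertebra localization in full chest
  volumes, no 3-D texture.
* The phantom does not model acquisition physics (kernel, dose, beam
  hardening) or anatomy; see the simulator caveats above.
* In-sample fit statistics only, faithful to the analysis design being
  reproduced; no cross-validation or bootstrap uncertainty.
* The DICOM adapter reads a single pre-selected axial file; PACS
  query/series handling is out of scope.
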