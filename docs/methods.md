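# Methods

This note documents the models, parameters and numerical choices behind
`drusemap`, and what the synthetic phantoms do and do not establish.

## Registration

Each spectral channel (FAF, IR, green SLO) is mapped onto the reference
color-fundus-photograph grid by a 2-D linear transform fitted by least
squares to paired vessel-bifurcation landmarks — conventionally eight
pairs, which over-determine the default 6-parameter affine model. A
4-parameter similarity model is available for poorly conditioned layouts.
Coordinates are (row, col), 0-based, origin top-left, pixel centers at
integer positions, everywhere in the package. Resampling is bilinear with
fill value 0 outside the moving-image footprint; filled pixels are
excluded from analysis by the macular mask and from the background
estimate (below). On noise-free landmarks the fit is exact to machine
precision; with 0.5 px isotropic landmark jitter the residual RMSE stays
below 1.5 px. Degenerate geometry (fewer than 3 non-collinear pairs for
affine, 2 for similarity) raises a distinct error. The interactive
alignment tools used in clinical practice do not expose their transform
family; the affine choice is this package's own, and an automated
surrogate for visual flicker checking (landmark residual RMSE plus image
normalized cross-correlation) is provided for logging.

## Preprocessing

Fixed order: grayscale → background correction → contrast stretch →
macular mask.

* **Grayscale**: integer rasters are scaled by their bit-depth maximum;
  RGB collapses through Rec. 601 luminance weights. Values live in [0,1].
* **Background correction**: the Gaussian-blurred image is subtracted
  from the original; the signed residual is re-centered at 0.5 and
  clipped, preserving local contrast symmetrically (clustering uses
  relative, not absolute, values). `blur_sigma` defaults to 50 px, chosen
  for a ~768 px macular frame: the scale must exceed the largest druse so
  lesions survive the subtraction. When a validity mask is supplied the
  background is a normalized (masked) convolution: registration fills
  out-of-footprint pixels with 0, and letting those zeros enter a wide
  blur would drag the background estimate down across half the field —
  this was observed directly and is the single most important numerical
  safeguard in the pipeline.
* **Contrast stretch**: linear rescale mapping the 0.2 and 99.8 percent
  quantiles (0.4% total saturation, split per tail) to 0 and 1, computed
  over in-mask pixels; a constant image is passed through with a warning.
* **Macular mask**: by default a centered disc of radius 45% of image
  width; a binary template may be supplied instead. Downstream statistics
  operate on the in-mask index set, never on zeroed pixels.

## Spectral theme classification

Pixels are 3-vectors (FAF, IR, green). Lloyd's k-means starts from
k = 16 with deterministic farthest-point seeding (seeded first pick, then
repeatedly the point farthest from the chosen set) and stops when the
fraction of pixels changing assignment in an iteration falls below 0.01
(`min_threshold`) or at `max_iter`. Empty clusters are dropped;
within-cluster SSE is asserted non-increasing across iterations.

Class models are Gaussian: per-class mean and covariance, ridge-regularized
with 1e−6·I because 8-bit quantization can make within-class covariance
singular; classes under 4 pixels fall back to a regularized diagonal.
Pairwise separability uses the transformed divergence
D_T = 2(1 − e^(−D/8)) with the standard divergence D of two Gaussians;
D_T is symmetric, zero for identical models, and saturates at 2. While any
pair falls below the criterion D_T ≥ 1.5 (associated in the remote-sensing
literature with > 83% correct pairwise classification; the mapping is
empirical and not recomputed here), the least-separable pair — ties break
to the lowest id pair — is replaced by its pixel-count-weighted mean and
k-means is re-run at k − 1 seeded from the merged centroid set, so k
strictly decreases and the loop ends in at most k_init − k_floor merges.
k_floor = 2 prevents a vacuous single-class map. The final map records the
k trajectory, the D_T matrix and which exit condition fired.

The "0.01 minimum threshold" of the original tooling is ambiguous; this
package treats it as the assignment-change convergence threshold. The
alternative reading — a minimum class population fraction — is implemented
as an optional post-fit filter (`min_class_fraction`, default off) that
dissolves small classes into their nearest surviving centroids.

## Drusen assignment and change

A theme class is drusen iff the fraction of its pixels inside the expert
annotation reaches `overlap_threshold` (default 0.5, majority rule).
Pigmentary-abnormality classes are never pooled: they are dark
(especially on green) and cannot reach majority overlap with a drusen
annotation. The drusen mask is the pure union of the member pixels of the
assigned classes — the duochrome averaging-blur of the original toolchain
is deliberately omitted because blurring before binarization perturbs the
area (a blur+binarize majority filter was prototyped and did not reduce
boundary noise). Area is the foreground pixel count; percent change is
100·(A₂−A₁)/A₁ with categories progression (> +5), stable ([−5, +5],
endpoints inclusive per the stated "−5% to 5%" stable band) and regression
(< −5). Edge cases: both areas zero ⇒ 0% stable; zero baseline with
nonzero follow-up ⇒ "incident drusen", percentage undefined, category
forced to progression with a warning and a flag.

## Evaluation statistics

Confusion counts are expert rows × method columns over the fixed
3-category vocabulary. Agreement = trace/n. **Sensitivity is
direction-aware**: among expert-changed eyes, only a same-direction call
counts as a detection — a regression eye called progression is a miss.
This is the only definition that reproduces both printed sensitivities
(22/22 and 14/22) from the same per-subgroup counts, which the test suite
asserts as a cross-consistency check. Specificity is the fraction of
expert-stable eyes called stable; with no stable (or no changed) eyes the
statistic is None, never silently 0. An expert-changed eye called in the
opposite direction is additionally flagged because its role in specificity
is undefined; it is counted only as a sensitivity miss. Bland–Altman
reports bias, bias ± 1.96·sd limits, and the correlation of difference vs
pairwise mean; Pearson r comes from scipy and is cross-checked against a
direct-formula oracle in the tests. The bundled cohort grading table
carries the observed 33-eye categorical counts; its per-eye percent
columns are synthetic illustrative values consistent with the categories
(stable-eye false positives use the reported 23–33% range); per-eye
percent values are not part of the reported counts.

## Synthetic phantoms

The generator emulates the spectral structure the method relies on, in
abstract pixel units (no device scale metadata is modelled):

* frame 192×192 px, macular mask radius 45% of width — the package's
  chosen working scale, at which the default 50 px background blur acts as
  near-global background subtraction;
* 3–5 drusen per eye (4 by default), radii 10–15 px, scattered within 34%
  of the width around the center so grown lesions stay in-mask and the
  local lesion density stays low (clustered bright lesions would carve
  deep halos under background subtraction);
* two concentric drusen zones, center (0.32, 0.29, 0.27) and edge
  (0.27, 0.24, 0.22) contrast units above background on (FAF, IR, green) —
  a modest apex/shoulder difference, as in soft drusen — bright on all
  channels;
* two pigment blobs, radii 7–11 px, dark predominantly on green
  (−0.30 green vs −0.06/−0.05 FAF/IR), emulating melanin absorption;
* three dark vessel lines (−0.12, half-width 1.5 px) on all channels, and
  eight ring-placed bifurcation-style landmarks;
* quadratic vignetting (amplitude 0.03), static background mottle shared
  by both visits (Gaussian-blob field, amplitude 0.02 — deliberately below
  the noise floor: strong smooth texture creates spectral continua that
  defeat the divergence merge loop), and per-pixel Gaussian sensor noise
  (σ = 0.025);
* per-channel similarity misalignment (≤ 4 px translation, ≤ 2° rotation,
  ≤ 2% scale) with exact landmark pairs, so registration is exercised;
  channels are sampled analytically on their own jittered grids — no
  interpolation in the synthetic raw data;
* expert annotation = truth mask under signed grader-noise morphology,
  default erosion by 1 px (a conservative grader outlining the unambiguous
  lesion extent). The conservative annotation makes the fate of
  lesion-boundary resampling classes deterministic: they never reach
  majority overlap, instead of flipping in and out of the drusen pool;
* longitudinal change by uniform scaling of all lesion radii, bisected
  until the rendered mask-area ratio matches the target within 1%
  (asserted); cohort targets draw uniformly from (+6, +40)% for
  progression, (−4, +4)% for stable, (−40, −6)% for regression, with the
  default cohort 11/11/11 mirroring a balanced three-subgroup design.
  All randomness flows from one seed through named streams (CRC32-keyed
  SeedSequence spawn), so adding a lesion type never perturbs existing
  draws and a single integer reproduces a cohort byte-for-byte.

### Phantom analysis configuration

`phantom_analysis_config()` departs from the library defaults in two
documented ways: theme classes smaller than 3% of the macular area are
dissolved (at this frame size such slivers are registration-resampling
artifacts, not tissue classes, and dissolving them keeps the two visits'
class structures commensurate), and the assignment threshold is 0.3
instead of 0.5 (matching the conservative annotation: a genuine
lesion-boundary class shows partial overlap with an eroded annotation).
With library defaults the pipeline still recovers change direction
reliably; these two settings are what bring the per-eye change-measurement
error below ±3 percentage points.

### What passing phantom tests do and do not show

The phantoms establish that the implementation is internally consistent:
exact registration recovery, the merge-loop contract, deterministic
outputs, correct area arithmetic, and that under the stated conditions the
pipeline recovers planted change directions (≥ 90% of eyes; 100% of eyes
with |change| > 10%) and change magnitudes to within ±3 points. They do
not establish clinical performance: real fundus images have anisotropic
texture, reticular pseudodrusen and other confounders, non-rigid
distortions, device-specific intensity transfer, and expert annotations
with structured (not morphological) disagreement. The phantom's lesion
contrasts are favorable by construction; on real data the method's error
is known to be substantially larger.

## Problem sizes and runtime

Default suite and acceptance runs use the 192 px phantom frame, a 33-eye
cohort (66 clustering runs at k ≤ 16 over ~58k in-mask pixels each), 50
random 24×24 stacks for the merge-loop property, and 100 seeded repeats
for the registration noise bound — about one minute in total on one CPU.

## Known limitations

* Drusen area only; no volume, no per-druse instance tracking, no mm²
  conversion.
* The k-means merge loop is path-dependent near the D_T = 1.5 criterion;
  per-visit class structure can differ between visits of the same eye,
  which is the dominant residual error source in change measurement.
* The phantom's change model (uniform radius scaling) does not cover
  de-novo lesion appearance except via the incident-drusen flag, nor
  lesion coalescence/fragmentation.
* Annotation disagreement between graders is modelled as a single
  morphological offset, not as structured, lesion-dependent variation.
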