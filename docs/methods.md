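# Methods

## The PTS score

A tissue label map assigns each pixel one of seven foreground classes
(cancer epithelium, stroma, lymphocytes, mucus, adipose, smooth muscle,
normal mucosa) or a reserved background label that never counts as tissue.
The tumor *region* is the morphological closing of the cancer-epithelium
mask: dilation followed by erosion with the same structuring element (SE).
Closing is extensive (never removes tumor pixels) and idempotent, and fills
gaps and holes narrower than the SE — the intra-tumoral spaces occupied by
reactive stroma. The PTS area is the number of stroma-labeled pixels inside
that region, including pixels outside the original tumor mask; the PTS
score is PTS area divided by the raw tumor-pixel count. The score is
scale-free, so label maps may be processed at any single downsample factor
as long as numerator and denominator use the same one.

Implementation: dilation and erosion are computed as FFT convolutions of
the binary mask with the SE footprint, thresholded at exact integer counts
(`≥ 1` for dilation, `= |SE|` for erosion). Pixels outside the image are
background; before closing, the mask is padded by the SE radius so the
dilation is never clipped at the array edge, and cropped back afterwards.
The test suite proves equality with the set-theoretic shift definition and
with a fully scalar double-loop definition on random mask/SE pairs,
including asymmetric footprints and off-center origins.

**SE choice.** Nothing in the score's definition fixes the SE; the default
is a disk of radius 64 px, i.e. ≈ 32 µm reach at 0.5 µm/px — wide enough to
bridge gaps larger than a gland lumen without annexing distant stroma. All
results record the SE used, and `--se-radius` exposes it. Enlarging the SE
never decreases the PTS area for openness-compatible nested SE families
(e.g. odd squares 1, 3, 5, 9, where each is the previous dilated by
itself); digitized disks are not exact homothetics and can violate the
nesting by an occasional boundary pixel, which is why the monotonicity
tests use squares and the disk monotonicity is asserted on hole fixtures.

An optional small-object filter (off by default) can drop tumor-mask
components below a pixel threshold before closing, for label maps distorted
by segmentation speckle.

## Stain normalization

Beer–Lambert optical density per channel is `OD = −log10(max(I/255, f))`
with floor `f = 1/255`; a pure-white pixel has OD 0 and the transform is
invertible above the floor. Macenko estimation discards pixels with
`‖OD‖ ≤ β` (default β = 0.15), takes the top-2 right-singular plane of the
remaining OD cloud (uncentered SVD), and reads the two stain vectors at the
α and 100−α percentile angles within the plane (default α = 1). Percentiles
use the inverted-CDF convention, which makes the estimate invariant under
exact pixel duplication. Signs are fixed so components are non-negative,
columns are unit-normalized, and hematoxylin is the column with the larger
red-OD component (ties are irrelevant in practice; the ordering makes
recomposition reproducible). Per-pixel stain concentrations solve a
2-variable non-negative least squares, closed-form vectorized over pixels
(verified against `scipy.optimize.nnls`); robust maxima are the per-stain
99th-percentile concentrations. Normalization rescales each stain's robust
maximum to the reference's and recomposes with the reference stain matrix.

Numerical notes: tiles with fewer than 100 pixels above the OD threshold
raise an explicit insufficient-tissue error; all quantization is
round-half-even; constant channels pass through histogram normalization
unchanged (any rescale would fabricate contrast). The pipeline order is
Macenko first, then per-channel histogram rescale — the order is a package
choice, fixed once. Idempotence of the normalization holds to ±2 intensity
levels at moderate staining; at high OD a single RGB level spans a large
concentration interval and quantization drift grows, and saturated channels
(intensity 0) are unrecoverable — round-trip properties are therefore
stated below saturation.

## Segmentation

The segmenter is a U-Net: per level, two 3×3 same-padding convolutions with
batch normalization and ReLU, 2×2 max pooling on the way down, 2×2
transposed-convolution upsampling with encoder-feature concatenation on the
way up, and a 1×1 convolution head over the seven classes. Defaults: depth
4, 16 base filters (doubling per level), Adam at learning rate 1e-3, batch
8, input 512 px. It is implemented directly on numpy (im2col convolutions
and explicit gradients), which keeps training bit-deterministic under a
fixed seed; the intended operating scale is desk-size experiments — tens of
pixels per tile and a few dozen tiles — not GPU-scale slide archives. The
architecture, loss, and stopping rule are identical at either scale; only
the problem sizes differ.

Training patches smaller than the network input are reflect-padded
(mirrored without repeating the edge pixel, extra pixel bottom/right; pads
larger than size−1 iterate the mirroring); larger images are tiled into
input-size windows at inference and stitched. The 80/10/10
train/validation/test split stratifies by each tile's majority class with
exact largest-remainder counts.

**Early stopping.** After each epoch the validation mean DSC is the mean
over patches of the mean Dice over classes present in truth or prediction.
An anchor epoch advances whenever the DSC improves on it by at least 0.1 %
*relative* (the absolute reading 0.001 nearly coincides near DSC ≈ 0.9);
training stops once `patience = 10` epochs pass the anchor, and the weights
returned are those of the raw-maximum epoch, not the last. The rule is
exposed as a pure function over scripted DSC sequences and tested against
an independent five-line transcription of its statement.

**Dice reporting.** Per class: mean, sample SD, and normal-approximation
95 % CI (mean ± 1.96·SD/√n) over the patches where the class occurs in
truth or prediction; a class absent from both masks scores a vacuous 1.0
and is excluded from averaging so correctly predicted absence neither drags
nor inflates the mean. An overall row pools all included (patch, class)
values. CIs over patches are an assumption; bootstrap CIs would be a
drop-in alternative.

A multi-level Otsu tissue/background pre-mask (`tissue_threshold`,
brightest stratum = glass) is provided for real slides; it plays no role on
synthetic data, where background is exact.

## Synthetic data: what it emulates and what it does not

*Tiles* carry per-class base RGB colors (a loose H&E caricature: dark
purple tumor epithelium, pink stroma, deep blue lymphocytes, …), Gaussian
RGB noise clipped to [0, 255], optional block-wise texture grain, and
either one class per tile or four classes in quadrants. Class colors must
be pairwise separated by a stated margin (default 20 RGB units, Euclidean)
or the spec is rejected — separability is the property that makes the
segmentation task well-posed. Class assignment is round-robin, so
proportions are balanced by construction.

*Slides* are axis-aligned rectangle geometries — tumor box, disjoint stroma
holes strictly inside it, optional exterior stroma band, optional filler
class — so every area is an exact integer pixel count and the expected PTS
score of a fillable-hole geometry is exactly Σ hole areas / tumor area.
Axis alignment avoids anti-aliasing ambiguity.

*Cohorts* draw the PTS score from a Beta distribution scaled to [0, 1.2]
matched to target mean 0.380 and SD 0.285 (the published cohort's observed
moments; non-negative, right-skewed, allows scores > 1), then LNM as
Bernoulli(expit(β0 + β1·score)) with defaults β1 = ln 29.654 ≈ 3.39 (the
published per-unit odds ratio) and β0 ≈ −1.69, set so the marginal LNM
prevalence at the mean score is the published 40.2 %. Invasion flags LI/PI/
VI are drawn independently given LNM with conditional probabilities taken
from the published 2×2 counts, then masked to missing at the published NA
rates; the N-stage among LNM-positives splits 70/30 between N1 and N2, and
the T-stage follows the published marginal distribution. The
conditional-independence of the flags given LNM is a modeling choice — no
joint distribution is published.

Passing tests on these data establish that the *computations* are correct
— exact morphology, calibrated intervals, a training loop that learns a
separable task, a deterministic pipeline. They do not establish performance
on real H&E: no nuclear texture, scanner artifacts, stain heterogeneity,
folds, or annotation noise are modeled, and a seven-color palette is
learnable by construction in a way real tissue is not.

## Cohort analysis

Patients are LNM-positive iff N-stage ≠ N0 (stage III vs I–II). The
exclusion ledger applies rules sequentially — rectal primary, inadequate
image, distant metastasis — attributing each record to the first matching
rule, so counts always reconcile: input = output + Σ ledger. AnyI is yes if
any of LI/PI/VI is yes, missing if none is yes and any is missing (absence
cannot be asserted from incomplete data), else no.

Descriptives use pooled-variance Student's t (the named test; not Welch)
and Pearson chi-square without continuity correction, excluding NA rows
from the test but displaying them as their own category. Logistic fits are
maximum likelihood (statsmodels) with Wald 95 % CIs, exp(β ± 1.96 SE);
complete or quasi-complete separation is flagged with unbounded CI rather
than reported as a silently huge odds ratio. For a binary predictor the
fitted odds ratio equals the contingency cross-product ratio, which the
tests assert to 4 significant figures. AUC uses the Mann–Whitney midrank
identity; its CI uses the DeLong structural-components variance. The
subgroup analysis partitions on T-stage exactly as {T0, T1, T2} vs
{T3, T4} and reports cells with fewer than two events (or two non-events)
as NA.

## Problem sizes and determinism

Default experiment scales: training uses 70 quadrant tiles of 24 px
(padded to a 32 px input, depth 3, 8 base filters, ≤ 20 epochs); the
end-to-end run segments five 96×96 slides with a disk SE of radius 8;
coverage simulations use 200 cohorts of n = 2000. All randomness flows from
one root seed through independently spawned child seeds per stage, model
checkpoints are written with fixed zip timestamps, and the run manifest
records SHA-256 checksums of every output so rerun determinism is a
checkable claim rather than an assumption.

## Known limitations

- The numpy U-Net is single-threaded and desk-scale; it is not a route to
  training on a 100k-patch archive.
- Stain normalization assumes exactly two stains plus residual; no
  Reinhard/Vahadane alternatives.
- Whole-slide pyramid formats (SVS/NDPI) are out of scope; inputs are
  PNG/TIFF tiles and label maps.
- Published cohort-level effect sizes (mean PTS 0.380, AUC 0.677,
  OR ≈ 29.7) depend on the original slide archives and are used here only
  as generator defaults, never as test targets.
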