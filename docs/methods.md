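# Methods

`sevseg` detects and segments small extracellular vesicles (sEVs, ~30-200 nm)
in transmission electron microscopy (TEM) images and measures their
morphology. This note documents the model, the numerical choices, the
synthetic data the package validates itself on, and the limits of what those
validations show.

## Pipeline

1. **Scale normalization.** Each image is resampled to a common reference
   pixel size of 1.56 nm by nearest-neighbour sampling, so the network can
   learn the absolute size range of vesicles and discard objects that are too
   small or too large. Nearest-neighbour sampling preserves the original
   intensity values exactly. Output dimensions are `round_half_up(shape *
   pixel_size / 1.56)` per axis; each output pixel copies the input pixel
   whose centre is nearest to its back-projected centre (ties to the larger
   index). Pixel sizes are supplied per image (CLI flag or CSV manifest), not
   read from TIFF tags, because TEM vendors store calibration in incompatible
   dialects.
2. **Tiling.** The normalized image is cut into overlapping 400 x 400
   patches. The overlap fraction is a free design choice; the default stride
   is 200 px (50% overlap), configurable. Partial edge tiles are completed
   by symmetric (mirror) padding at the bottom/right: padded content is then
   statistically indistinguishable from real image content, so edge tiles
   keep a meaningful contrast stretch and the network is never shown filler
   values outside its training distribution. Each patch is independently
   contrast-normalized by linear stretching of its intensity histogram to
   [0, 1]; a constant patch maps to all zeros (the stretch is undefined
   there and zero is the background level).
3. **FRU-Net.** A fully residual U-shaped network (below) maps each patch to
   a per-pixel vesicle probability.
4. **Stitching.** Patch predictions are blended by the arithmetic mean over
   all patches covering a pixel. Mean blending was chosen over max or
   centre-weighted blending because it is order-independent and exactly
   testable against a sum/count accumulation.
5. **Binarization and cleaning**, in this fixed order: threshold at tau
   (foreground iff p >= tau); remove components touching the image border;
   binary closing with a 2 px disk; fill holes; remove components smaller
   than pi * 15^2 nm^2 (~706.9 nm^2, the area of the smallest object still
   countable as a 30 nm vesicle). The area rule is stated in nm^2 and
   converted to pixels at the working scale (~290.5 px at 1.56 nm/px), so it
   is magnification-independent. Components and filled holes use the
   standard 8-/4-connectivity duality. The border rule precedes closing,
   following the stated order of operations; a closing could in principle
   reconnect an object to the border afterwards, which we accept as defined.
6. **Radon splitting** of touching vesicles (below).
7. **Restoration.** The labeled mask is upscaled to the original image size
   by nearest neighbour; each label is then smoothed independently — Gaussian
   blur (sigma 3 px) of its binary mask, re-thresholded at t = 0.4. The
   threshold sits slightly below 0.5 so the object keeps its size (0.5 would
   preserve a straight edge exactly; 0.4 compensates the curvature loss of
   convex outlines). Labels never merge: overlaps go to the smaller label
   index. For vesicle-sized objects (radius above ~30 px at original scale)
   the smoothed area stays within 5% of the input area; for objects near the
   minimum size the growth can reach ~7%.

## The network

The FRU-Net is a U-shaped encoder-decoder with pre-activation residual
layers (`ELU - 3x3 conv - dropout - ELU - 3x3 conv`, summed with the input
without scaling) at every level:

* **Contracting path** (3 levels, channels 32/64/128 at base width 32): a
  3x3 convolution sets the level width, a residual layer follows, then 2x2
  *average* pooling. Average pooling suits smooth round objects better than
  max pooling.
* **Connection step**: 3x3 convolution to 256 channels plus a residual
  layer; no pooling.
* **Expanding path**: 2x2 nearest-neighbour upsampling, concatenation with
  the same-level contracting features, then a residual layer that takes the
  concatenation directly: an independent 1x1 convolution projects the
  concatenated maps for the residual sum, while the branch's first 3x3
  convolution performs the matching channel reduction.
* **Head**: a 3x3 convolution refines the feature vectors; a 1x1 convolution
  with sigmoid yields the probability. All convolutions are zero padded, so
  output size equals input size; any input with both sides divisible by 8
  works.

Design points the architecture description leaves open, and how they are
resolved here: upsampling is nearest-neighbour resize followed by the 1x1
channel-reducing convolution (rather than transposed convolution); weights
are He-uniform initialised from the estimator's seed; the output 1x1
convolution is zero-initialised so an untrained network predicts exactly 0.5
and the first updates are well scaled; dropout sits between the two
convolutions of each residual layer, in the listed order. A JSON
architecture manifest (layer list, channel widths, hyperparameters) is
written next to every checkpoint.

Training uses binary cross-entropy, Adam (default lr 1e-4, batch 10, 100
epochs), and a validation split of 10% of the *real* patches taken before
augmentation; validation patches are never augmented or trained on, and the
weights of the epoch with the lowest validation loss are kept. Augmentation
(optional, `n_aug` copies per patch) samples horizontal/vertical flips,
quarter rotations and +-10% zoom — a family suited to orientation-free round
objects — applying the same geometric transform to patch and mask (mask
warped nearest-neighbour, so it stays binary).

The network, its gradients and Adam are implemented in-package on NumPy,
with numba kernels for the 3x3 convolutions (NCHW float32 layout; the
backward pass reuses the forward kernel on flipped, channel-transposed
weights). Gradients are validated against central finite differences in the
test suite. Inference is deterministic (dropout off); training is
deterministic given the estimator seed.

## Radon splitting

Touching round objects form one connected component whose neck is crossed
by a short line: the line integral across the neck is a local minimum of
the projection profile, flanked by the two body maxima. The sinogram is
computed by exact binning: each foreground pixel contributes its unit mass
to the two nearest offset bins (linear weights) of its signed distance from
the component centre, for every angle in a 0-179 degree grid (1 degree
step). Linear binning conserves each column's mass exactly and suppresses
the lattice aliasing that plain nearest-bin counting exhibits at diagonal
angles (which would otherwise fabricate deep minima on single discs; a
~13% aliasing *maximum* remains at exactly 45 degrees and is harmless).

A minimum qualifies when its value is at least `min_depth = 0.2` below both
flanking maxima. The depth threshold was chosen against the paired
requirements that >= 90% of generated touching-disc pairs (overlap 2-15% of
the radius) split into exactly two labels while < 5% of single near-round
objects (axis ratio <= 1.3) split at all; true necks in that regime are
40-70% deep while digitisation ripple stays below ~10%. Candidate minima
are tried deepest first (ties: smaller angle, then smaller |offset|); a cut
is realised as the exact pixel band within +-0.75 of the minimum's offset —
a band of total width 1.5 px is the narrowest cut that disconnects an
8-connected component (two 8-adjacent pixels differ by at most sqrt(2) in
projection offset). A split is accepted only if it produces >= 2 fragments
that all pass the minimum-area rule; otherwise the next candidate is tried
and, failing all, the component is left intact (this protects single
vesicles from having slivers shaved off). Accepted fragments are re-examined
recursively, so chains of three or more vesicles resolve.

The per-angle 1-D minimum rule is an approximation of a 2-D sinogram "hole"
criterion; with the depth threshold above, the two behave identically on
convex bodies.

## Evaluation measures

Detection follows the Cell Tracking Challenge protocol. A GT object `g` is
detected by a predicted object `s` iff `|g n s| > 0.5 |g|` (at most one `s`
can qualify). `DET = 1 - min(AOGM_D, AOGM_0) / AOGM_0` with
`AOGM_D = 5 NS + 10 FN + 1 FP` (the standard detection weights, exposed in
config) and `AOGM_0 = 10 |GT|`; a predicted object claiming k >= 2 GT
objects contributes k-1 NS (split) operations. SEG is the mean Jaccard over
all GT objects (undetected objects score 0); SEG* restricts the mean to
detected objects. The false-positive ratio is FP/(FP+TP).

Morphometry: area `A` from the pixel count, perimeter `P` from the
four-direction Crofton estimator — step-counting an 8-connected digital
contour underestimates smooth curve length and would bias the roundness
`r = 4 pi A / P^2` of digitised discs far below 1, while Crofton is
asymptotically unbiased for convex shapes (digitised discs may come out
slightly above 1; values are reported unclamped). Diameter is the
equivalent-circle diameter `d = 2 sqrt(A/pi)`. Relative errors between a
GT and a predicted measurement use `delta = 1 - min/max`, symmetric and in
[0, 1). Measurements are taken on the final original-scale smoothed mask.
Across digitised discs of radius 15-100 px the mean relative diameter error
is below 2% and roundness stays within 5% of 1. Cross-method roundness
comparisons carry an estimator caveat: the convention used for any external
reference measurement may differ.

Distribution comparison uses a Monte-Carlo subsampled two-sided Wilcoxon
rank-sum test: per fold, 30 values (or 2/3 of the sample when it is smaller
than 30) are drawn without replacement from each set; the number of folds is
`floor(10 * sample_size / fold_size)` with `sample_size = min(n_gt,
n_pred)` when the sets differ in size; the mean p over folds is reported.
The scipy Mann-Whitney implementation is used with the exact method for
folds smaller than 10 values and the tie-corrected normal approximation
otherwise. Under the null (same distribution), the mean p averaged over
replicates sits near 0.5.

## Synthetic scenes

The generator emulates negatively stained sEV TEM imaging: near-circular
vesicles (diameters uniform in 30-200 nm, ellipticity up to 1.2) with a
bright lumen and a darker stained rim (~10 nm wide), on a mid-gray
background that is either smooth or coarse-grained; optional clusters of
touching vesicles (distinct labels sharing a boundary, centre distance
1-3 px short of the radius sum) and irregular dark artifact blobs excluded
from the ground truth. Grain is low-pass filtered Gaussian noise at a
configurable grain scale — a visual match to coarse backgrounds, not a
physical TEM noise model. Scenes are bit-reproducible from their seed, and
the analytic per-vesicle truth (equivalent-circle diameter; roundness of
the generating ellipse via the exact elliptic-integral perimeter) is
recovered by the package's own morphometry within 2%.

What passing on synthetic scenes does *not* show: real TEM backgrounds have
structured debris, stain gradients and cup-shaped (deflated) vesicles that
the generator does not render; real annotation boundaries carry human
variability. Synthetic results therefore validate the pipeline's mechanics
and internal consistency, not its accuracy on real micrographs.

## Scaled-down end-to-end protocol

`sevseg.protocols` trains a reduced network — base width 8, 15 epochs, 40
synthetic 400 x 400 patches — and scores it on 10 held-out 512 x 512
synthetic scenes (tau 0.5). These sizes keep a full run in minutes on one
CPU while still exercising scale normalization, tiling, stitching,
cleaning, splitting, restoration and scoring together. Because the run has
only 300 Adam updates (batch 2), the protocol uses a step size of 1e-3
rather than the full regime's 1e-4, which cannot leave the
constant-prediction plateau in so few updates. The binarization threshold
is the general default tau = 0.5.

## Known limitations

* The area filter sits exactly at the area of a 30 nm vesicle, so objects
  at the lower end of the size range are detected marginally: a predicted
  mask only slightly smaller than truth falls under the cut-off. This is a
  property of the method, visible in the synthetic protocol as missed
  30-35 nm vesicles.
* The splitting criterion assumes convex, round bodies; elongated or
  cup-shaped objects can be split spuriously (bounded by the <5%
  false-split rate in the round regime only).
* Measurements on clusters depend on the cut placement; the 1.5 px cut band
  removes a small amount of genuine vesicle boundary.
* The NumPy/numba network trains at CPU speed: suitable for the reduced
  protocol and for inference, not for full-scale training on the real
  benchmark.
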