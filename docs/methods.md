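# Methods

This note documents the models, conventions and numerical choices behind
`skelpatch`, in the order of the pipeline.

## Synthetic phantoms

**What is emulated.** TOF-MRA renders flowing blood bright on a dark
background. A phantom is a 3D grid (default 128³, desk profile 96³, at
0.3 mm isotropic spacing) containing:

* *Vessels*: tubes of constant radius (default 0.5–3 mm; desk profile
  0.6–1.1 mm) around random cubic-spline centerlines that run face-to-face
  through the volume. Tubes are rasterized by stamping discrete balls along
  the densely sampled centerline; endpoints extend past the volume faces so
  no end caps appear inside the grid (this makes the analytic cylinder
  volume π r² L an exact oracle for straight tubes). `curviness = 0`
  degenerates to an axis-aligned straight tube.
* *Aneurysms*: ellipsoids with axis ratios drawn uniformly in [0.7, 1.3]
  (normalized so the longest axis equals the drawn diameter) and uniformly
  random orientation, centered on a vessel wall (centerline point plus 0.8
  vessel radii along a random normal) so the bulge always touches the lumen.
  Diameters follow the clinical mixture: strata < 5 / 5–10 / > 10 mm with
  probabilities proportional to 130 : 21 : 3 and uniform density within each
  stratum, truncated to the requested range and to what fits the volume.
  The clinical distribution is reported by strata counts only; the uniform
  within-stratum choice is the simplest density consistent with them.
* *Intensity model*: piecewise-constant image (background 50, vessel 300,
  arbitrary units — contrast is a free parameter because acquisition
  intensity scales vary by scanner), multiplied by a random quadratic
  polynomial bias field normalized into [1−a, 1+a] (default a = 0.2), then
  Rician-corrupted: I ← √((I+ε₁)² + ε₂²), ε ~ N(0, σ²). Rician is the
  physically correct magnitude-MR noise law; the smooth multiplicative field
  mimics coil/positioning inhomogeneity and gives the bias-correction stage
  something real to remove.

**What is not emulated:** partial-volume edge blur, flow artifacts,
skull/scalp tissue, vessel caliber tapering and bifurcation geometry.
Passing tests on phantoms therefore demonstrate the pipeline's mechanics
(sampling correctness, topology preservation, learnability of a bright
bulge-on-tube signal), not clinical-grade performance.

## Preprocessing

Order of operations: **bias correction → isotropic resampling → percentile
clip + z-score**. Bias correction must see raw intensities (the
multiplicative model is destroyed by standardization), and standardization
is performed last so the network input is always mean-0/std-1.

* *Clipping*: intensities are clipped to the [0.5, 99.5] percentile interval
  of the volume; percentiles use linear interpolation between order
  statistics (numpy's default), which the test oracle mirrors. The z-score
  uses the clipped volume's mean/std, so output mean/std are exactly 0/1.
  Statistics are computed per volume (not within a brain mask); on phantoms
  without skull the difference is immaterial.
* *Bias correction*: default backend fits a quadratic polynomial to
  log-intensities by least squares and divides it out (normalized to mean 1
  in the mask). The fit uses only voxels inside the [2, 90] percentile band
  of the masked intensities, so sparse bright vessels do not masquerade as
  inhomogeneity. Contract (enforced, with passthrough otherwise): the
  within-mask coefficient of variation never increases. An N4 backend via
  SimpleITK is selectable (`method="n4"`). Masks of fewer than 100 voxels
  are refused with a warning (passthrough).
* *Resampling*: trilinear for images, nearest-neighbor for masks (so masks
  stay strictly {0,1}), target 0.3 mm isotropic; the output grid preserves
  physical extent to within one voxel per axis.
* *Brain masking* is pluggable (`none`, Otsu `threshold`, `file:<path>`):
  phantoms carry no skull, and the clinical skull-stripping model is not
  redistributable, so the step is an interface, not a model.

## Skeletonization

Five steps on the preprocessed volume: intensity threshold (fixed value or
percentile, default 99th), 26-connected component filtering (default
minimum 3000 voxels at 0.3 mm, rescaled by (0.3/spacing)³ at other
spacings; the desk profile uses 500 because its vessels are thinner),
region growing (26-neighbor propagation accepting intensities down to
threshold − 0.10·|threshold|, a fixpoint iteration that can only add
voxels and is bounded by the relaxed-threshold superset), morphological
closing (ball structuring element, radius 1 voxel, computed on a padded
array so closing stays idempotent at borders), and thinning.

Thinning runs a published topology-preserving parallel 3D thinning
(directional sub-iterations, foreground 26- / background 6-connectivity)
followed by a deterministic raster-order sequential sweep that deletes any
remaining *simple, non-endpoint* voxel using the standard local criterion
(exactly one 26-connected foreground component in the punctured 3³
neighborhood and exactly one 6-adjacent background component). Endpoints
(≤ 1 foreground 26-neighbor) are preserved — a bare curve would otherwise
erode to a point. The result is a fixpoint: subset of the input, same
26-component count, no deletable voxel; the test suite verifies these
against an independent global-topology oracle (component counts plus Euler
number before/after deletion).

## Patch sampling

* *Positives* are sampled per 26-connected aneurysm component,
  **non-centered**: the patch origin is uniform over the whole box of
  origins whose patch contains the component's full mask (the admissible set
  is a per-axis interval product, which a brute-force enumeration oracle
  confirms). Components larger than the patch raise an error naming the
  component. Default 10 positives per aneurysm (desk profile 2).
* *Negatives* are centered on skeleton voxels at least 5 mm from any
  aneurysm voxel **and** verified aneurysm-free by an explicit crop check —
  the distance filter alone cannot guarantee purity once the patch
  half-extent exceeds the exclusion radius.
* *Ratio control* is global and exact: |negatives| = k·|positives|,
  k ∈ 1…5, with the negative quota round-robined over cases (ordered by
  case id). All sampling is per-case seeded (a hash of the plan seed and the
  case id), so the dataset is invariant to cohort ordering and bit-identical
  across reruns.
* *Borders*: volumes are conceptually zero-padded by half a patch per axis;
  origins may be negative. Post-standardization background is near but not
  exactly 0; the approximation only affects patch margins at the volume
  boundary.
* *Augmentation* (flips, rotation ±15°, zoom 0.9–1.1, Gaussian/Rician noise
  at 1–5 % of the intensity range, blur, contrast 0.9–1.1, gamma 0.8–1.2):
  geometric transforms are applied jointly to image (trilinear) and mask
  (nearest-neighbor), intensity transforms to the image only; the label is
  recomputed from the transformed mask, and a transform chain that evicts a
  positive patch's entire lesion is resampled (bounded retries). Ranges are
  conservative so sub-5 mm lesions survive. The desk training profile
  disables augmentation; it is exercised by its own tests.

## Network

A 3D U-Net operating channels-last on (N, D, H, W, C):

* encoder blocks of two 3×3×3 same-padding convolutions, each followed by
  batch normalization and PReLU, with 2×2×2 max pooling between levels and
  channel doubling per level; a bridge block; a decoder of nearest-neighbor
  2× upsampling, a channel-halving 1×1×1 "up-convolution", concatenation
  with the skip connection, and another two-conv block; final 1×1×1
  projection to a sigmoid voxel-probability map. At depth 4 the builder
  reports 23 convolutional layers (8 encoder + 2 bridge + 4 up + 8 decoder
  + 1 final). Same-padding is used so 64³ patches map to 64³ outputs;
  unpadded convolutions would shrink a depth-4 3D patch below usable size.
* optional residual blocks (shortcut, 1×1×1 projection on channel change)
  and an optional dual-attention block at the bridge (position and channel
  self-attention, each added through a scalar gate initialized at zero so
  the block starts as the identity).
* auxiliary classification heads (global average pooling → linear →
  sigmoid) attachable at the bridge and mid-decoder nodes (configurable).
* the final projection's bias is initialized to −3, i.e. a ≈ 0.05
  foreground prior, so optimization starts from the overwhelmingly correct
  background call and the Dice/Tversky gradients act on the lesion from the
  first step.

**Losses.** Segmentation loss = soft Dice + Tversky focal
(α = 0.3, β = 0.7, γ = 4/3 by default — false-negative-weighted, the usual
choice for small lesions) + voxel binary cross-entropy, all with the
smooth = 1 stabilizer; the Dice term is algebraically the
α = β = 0.5, γ = 1 member of the Tversky focal family, so the identity
Tversky(½, ½, 1) ≡ Dice is exact. Per-sample reduction over spatial axes,
mean over the batch; with smooth = 1, all-zero-target patches (the common
case under skeleton sampling) still drive false-positive suppression
instead of saturating. With auxiliary heads enabled the total is the
average of the segmentation and classifier losses. BCE probabilities are
affinely squeezed into [ε, 1−ε], ε = 10⁻⁶, keeping gradients finite.

**Training.** Adam (β = 0.9/0.999) at learning rate 10⁻³, batch 16, up to
500 epochs in the reference profile; the desk profile uses batch 4,
learning rate 5·10⁻³ and single-digit epochs so a training fits in minutes
of one CPU core (smaller batches give more optimizer updates per
sample-pass, which dominates convergence at this scale). Two standard
stabilizers guard the short aggressive schedules: global gradient-norm
clipping (default 10) and cosine learning-rate decay to a 0.1× floor —
without them, late-schedule training at elevated learning rates can
collapse the segmentation head to all-background. Best-validation
parameters are restored after training; non-finite loss aborts with a
diagnostic. One master seed fans out to phantom generation, splitting,
sampling, augmentation and weight initialization.

**Inference.** Patches are tiled along the skeleton (one tile per
stride-sized cell of skeleton voxels, default stride = half patch),
probabilities averaged over overlapping tiles; voxels never covered by a
tile keep probability 0; binarization at 0.5. Patch-level classification
uses the mean auxiliary-head probability (> 0.5); without auxiliary heads
the fallback rule calls a patch positive when the binarized segmentation
contains at least `fallback_min_voxels` (default 10) voxels.

## Evaluation

Confusion counts and the accuracy/sensitivity/specificity/PPV/NPV panel are
computed at patch level; DSC at case level, reported as mean ± std over
cases. A case where both ground truth and prediction are empty has no
defined DSC and is excluded from the mean (tracked separately) rather than
scored 0 or 1. Zero-denominator panel entries are reported as undefined
(`None`), never 0. Size strata < 5 / 5–10 / > 10 mm partition annotated
cases; empty strata are reported with count 0 and NaN metrics.

## Experiment orchestration

Cases are split by patient (never by patch) into train/validation/test with
largest-remainder apportionment of the 120 : 19 : 15 proportions (floors
plus largest fractional remainders, ties in train→val→test order). All
sweep cells (ratio 1:1…1:5 × auxiliary on/off) share one cohort and one
split, so comparisons are paired; cells are persisted as JSON and sweeps
are resumable. Reports are bitwise reproducible under a fixed master seed.

**Desk profile** (the CPU-sized configuration used by the test suite and
the acceptance script): 96³ phantoms at 0.3 mm with 2 vessels (radius
0.6–1.1 mm) and one aneurysm of 2.5–6 mm (the upper end bounded by what a
32³ patch can contain), 32³ patches, 2 positives per aneurysm, base-8
depth-3 network with bridge+mid auxiliary heads, batch 4, 5 epochs at
learning rate 5·10⁻³. These sizes were chosen so a full paired ablation
(two arms × three seeded 20-phantom cohorts) runs in minutes on a single
core; the reference profile (64³ patches, base 16, depth 4, batch 16, 500
epochs, learning rate 10⁻³) is selected by constructing the configs
directly.

## Known limitations

* The phantom's piecewise-constant intensities make vessel binarization
  easier than on clinical data; threshold selection strategies are exposed
  but only lightly stressed.
* The polynomial bias model is low-order; strongly non-polynomial fields
  should use the N4 backend.
* Desk-scale schedules stop long before convergence: held-out DSC under the
  desk profile is a direction-of-effect readout, not an estimate of
  attainable segmentation quality.
* Whole-volume prediction only scores voxels near the skeleton; an aneurysm
  missed by the vessel segmentation is invisible to the network — faithful
  to the design, but a real failure mode.
* The auxiliary classifier's headline benefit in the clinical regime is
  false-positive suppression along normal vessels under severe patch
  imbalance, a phenomenon of long training schedules on hard data. On desk
  phantoms — where the dominant error is missing small lesions and
  off-lesion probability mass is negligible — the classifier markedly
  improves patch-level discrimination, but averaging its loss with the
  segmentation loss halves the voxel head's effective gradient, so at
  desk-budget schedules (~120 optimizer steps) held-out DSC with the
  auxiliary head is at parity or slightly below the plain network. Volume
  inference therefore does not gate segmentation on the classifier's patch
  decision (on phantoms it could only remove lesions, not false
  positives); the gate is the natural extension in the clinical regime.
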