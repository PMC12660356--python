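# Methods

This note documents the models and procedures the toolkit implements,
the parameters that matter, the synthetic data it is validated on, and
the design decisions taken where the design was genuinely open.

## Enhancement chain

All three enhancers are monotone lookup tables on integer gray levels;
equal input levels always map equally, and the sorted order of pixel
values is preserved.

**Histogram equalization** uses the classic normalized-cdf map
`round((cdf(v) − cdf_min)/(N − cdf_min) · (GL − 1))`.  An image (or
tile) with a single occupied gray level is returned unchanged: a
constant region carries no contrast to stretch, and the formula's
denominator would vanish.

**CLAHE** pads the image by edge replication so tiles cover it evenly,
clips each tile histogram at `Q ·` (tile pixel count), redistributes
the clipped excess uniformly over all `GL` bins in a single pass,
equalizes each tile with the same cdf map, and blends neighbouring
tile mappings bilinearly in tile-center coordinates.  `Q` here is a
fraction of the tile pixel count (not of the uniform bin height);
the default `Q = 0.2` with 8×8 tiles gives a visible but clip-limited
stretch.  With `Q = 1` and one whole-image tile the code path reduces
bit-for-bit to global equalization — this identity is asserted in the
tests.

**Fuzzy contrast enhancement** composes fuzzification, intensification
and defuzzification per gray level.  Parameters:

| parameter | meaning | default | why |
|---|---|---|---|
| `FE` | exponential fuzzifier (membership curvature) | 1.0 | linear-in-distance membership; both printed worked examples use it |
| `FD` | denominational fuzzifier (grayness retained) | 2040 = 8·(GL−1) | keeps μ(0) ≈ 0.89, i.e. all memberships above the 0.5 crossover, so dark ultrasound frames are lifted toward the bright end — the regime in which the fuzzy enhancer is the brightness-maximising candidate |
| `gl_min`, `gl_max` | gray-level bounds | 0, 255 | 8-bit images |
| `crossover_n` | level mapped from μ = 0.5 | image median | the defuzzifier needs a crossover but none is prescribed; the median adapts it to each image's exposure |

The printed intensification operator maps μ = 1 to −1; the standard
operator `1 − 2(1−μ)²` is used for the upper branch so the fixed
points are {0, ½, 1} and the range stays [0, 1].  Defuzzified values
are rounded half-up to integers.

The scene-intensity model `Int = SR + L_α(1 − e^{−βd})` defaults to
`β = d = 1`, `SR =` image mean, `L_α =` image standard deviation; the
model's symbols are never bound to data in the derivation, so the two
image moments are used as the natural radiance/scattering surrogates.
PSNR is computed against the pre-enhancement image and reported
without thresholding.

## Preprocessing

Cropping binarizes at a configurable threshold (Otsu by default),
takes 8-connected components of the foreground, and crops to the
extreme points of the largest-area component (ties: first in row-major
scan).  An image with no foreground is returned unchanged.

Augmentation fans each original into 14 variants: horizontal flip,
vertical flip, and rotations by ±45°, ±90°, ±135°, ±180°, ±225°,
±270° in that order.  The signed pairs ±180 (and ±225/∓135 etc.)
coincide geometrically but are enumerated literally so the fan-out is
exactly 14 and 3,800 originals yield exactly 53,200 augmented images.
Rotations are about the image center with output shape preserved and
constant fill 0; 90°-multiples are dispatched to exact index
permutations (`np.rot90`), other angles resample with
nearest-neighbour interpolation by default so permutation oracles stay
exact.  Masks receive the identical transform.

Splitting is leakage-safe: the test set is drawn from original images
only, stratified per class; the val split is taken per *source image*
so an original and its augmented copies never straddle train/val.
Augmented copies of held-out test originals (possible only if
augmentation is run before splitting) are excluded from every
partition with a warning, since placing them anywhere would either
leak test content into training or put one source id in two
partitions.

## Architecture

FCAU-Net is a four-stage U-Net (two 3×3 conv + BN + ReLU per stage,
2×2 max-pool downsampling, bilinear-upsample + conv decoding, channels
doubling from `base_channels`) with:

* **Attention gates** on each skip connection: 1×1 projections of the
  skip and the (upsampled) gating signal are summed; the *modified*
  gate applies batch norm → ReLU → dropout (rate 0.1) before the final
  1×1 conv + sigmoid, the *default* gate omits BN and dropout — this
  is the toolkit's reading of the two gate variants in the ablation
  lattice.  The sigmoid coefficient map (one channel, broadcast)
  multiplies the skip features.
* **The FFC module** at the bottleneck.  Channel attention
  (row-softmax of the C×C Gram matrix) and position attention
  (softmax over (HW)×(HW) affinities, with 1×1 query/key/value
  projections) are applied with learnable scales β initialized to 0
  (residual-dominant start; identity at initialization), summed with a
  single shared residual.  A quarter-scale companion map is produced
  by two stride-2 3×3 convolutions — the quarter-scale shapes are
  asserted in the derivation but their provenance is not, so this is
  the toolkit's choice.  Fusion:
  `OFM = (pos₁ ⊙ con₂)(F) + 4 · Upsample(( con₁ ⊙ pos₂)(F¼))`, where
  pos₁ = depthwise 3×3 → BN → 1×1; con₁ = the same chain + sigmoid;
  con₂ = two stride-2 3×3 convs → BN → 1×1 → ×4 bilinear upsample →
  sigmoid; pos₂ = 3×3 stride-2 conv → BN → 1×1 → 3×3 stride-2 average
  pool.  The two stride-2 stages of pos₂ cannot preserve the
  quarter-scale grid if run on it directly, so they run on a ×4
  bilinearly pre-upsampled copy (¼H → H → H/2 → ¼H): both strided
  stages are literally present and the module's shape contract holds.
  The ×4 in the fusion is the literal scalar magnitude balancer,
  applied after the spatial ×4 upsample.
* A **classification head** (global average pool of the final decoder
  features → dense → softmax over healthy/infected) and an optional
  **mask head** (1×1 conv + sigmoid on the same features).  Pooling
  the *decoder* output keeps the gates and the FFC module in the
  classification gradient path, so the ablation switches are
  observable in classification behaviour.

The printed attention equations re-apply `exp` to already
softmax-normalized scores; the standard dual-attention form
(softmax-weighted sum × learnable scale + residual) is implemented, as
the surrounding derivation describes softmax-normalized weights.

Batch-norm ε is 1e-5 (momentum 0.1).  Training minimizes
class-weighted cross-entropy with Adam (batch 8 by default), plus a
soft-Dice term (weight 0.5) on the mask head when ground-truth masks
are supplied; none of loss, optimizer or learning rate is prescribed.
The default learning rate is 3e-3: across repeated seeded runs at the
64×64/base-8 study scale, 1e-3 converged to a separating classifier
within 30 epochs in only about half the runs, while 3e-3 did so in
most runs with milder failures, so the larger rate is the reliable
default for this small-batch regime.  Everything is seeded: weight
initialization from the model seed, shuffling/dropout from the
training seed; training twice with identical seeds yields identical
weights.

The network runs on a small bundled reverse-mode autodiff engine
(`fcaunet.nn`): im2col convolutions (dense and depthwise), pooling,
bilinear/nearest upsampling, batch norm, softmax, and fused
cross-entropy, each verified against finite differences in the test
suite.  Channel widths are configuration-driven (tests and study runs
use `base_channels = 8` at 64×64); published parameter counts of the
full-scale model are therefore not a reproduction target.

## Synthetic phantoms

The generator emulates the class structure of clinical PCOS
ultrasound: a speckled background (multiplicative gamma noise, shape
4 — characteristic ultrasound speckle), a darker elliptical ovary, and
hypoechoic disc follicles.  Healthy phantoms carry 1–3 large central
follicles; polycystic phantoms carry 8–15 small follicles in a
peripheral band (the "string of pearls").  Follicles are placed by
rejection sampling with pairwise separation so mask components stay
distinct; radii shrink as attempts accumulate, and a bounded number of
deterministic fresh layouts are tried before the generator raises.
Masks are the union of follicle discs.

In *easy* mode the class-conditional follicle counts are disjoint, so
the classes are perfectly separable by construction; in *hard* mode
the count ranges overlap.  Default images are 64×64 (configurable up
to 256) to keep a full train/evaluate cycle in minutes on one CPU;
the study-scale accounting runs (3,800 phantoms, 53,200 augmented
images) use the same generator.

What passing tests on phantoms do **not** show: robustness to real
speckle statistics, probe/depth-dependent attenuation, anatomical
variation, annotation noise, or class overlap in real cohorts.
Phantom results validate the *pipeline* (shapes, seeding, leakage
rules, optimization, metric arithmetic), not clinical performance;
published full-scale accuracies on the real benchmark are explicitly
out of reproduction scope.

## Evaluation and statistics

The positive class is "infected" everywhere.  Metrics with zero
denominators are reported as flagged nulls, never 0.  Report tables
round half-up to one decimal.  ROC/PR curves and areas come from
scikit-learn; the k-fold plan is a seeded shuffled partition with fold
sizes within one.

Grad-CAM targets the last decoder convolution by default; the heatmap
is the rectified gradient-weighted channel sum, bilinearly upsampled
and max-normalized (all-zero-safe).  The predicted region `P` is the
top-20% quantile of the heatmap (the construction of `P` is otherwise
unspecified).  IoU/Dice define both-empty as 1 (flagged); the
pointing game breaks peak ties row-major; the energy score is the
heatmap mass inside the ground-truth region.  On 64×64 phantoms with
a small model, Grad-CAM localization against follicle masks is
meaningful only when the mask head is trained (the classification
gradient alone concentrates on background context), and the
acceptance run therefore trains with masks and scores localization on
polycystic phantoms; localization percentages at this scale are far
below full-scale published values and are reported descriptively.

The paired t-test implements the textbook formulas literally: n−1
variance, `t = mean/(SD/√n)`, two-sided p from the t distribution,
95% CI `mean ± t_crit · SD/√n`; a zero SD is flagged (t = ±∞, or 0
with p = 1 when the mean is also zero).  McNemar reports the
continuity-corrected chi-square statistic `(|b−c|−1)²/(b+c)` on the
discordant counts, with an exact-binomial p-value (via statsmodels)
when the discordant total is below 25; identical predictions give
statistic 0, p = 1.

## Known limitations

* The engine is numpy-only and single-threaded beyond BLAS; it is
  sized for 64×64 study conditions, not full-resolution training.
* CLAHE's uniform single-pass redistribution slightly overfills bins
  that were already at the clip limit (the standard approximation).
* Grad-CAM localization on phantoms is fragile across seeds at this
  model scale (see above); only the classification metrics are stable
  quantities of the synthetic study.
* `hard` mode is provided for stress-testing separability assumptions
  and has no acceptance-grade expected values.
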