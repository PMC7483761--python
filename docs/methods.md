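# Methods

`cycleseg` localizes fluorescent cell-cycle nuclear markers (e.g. the
CYCB1;1 fusion protein that labels nuclei of dividing cells) in 3D
confocal stacks of growing *Arabidopsis* roots. The input is a time
series of volumetric images plus point annotations of nucleus centers;
the output is a per-voxel segmentation, a set of detected nuclei with
centroids, and precision/recall/F-measure scores at both the voxel and
the object level. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Ground-truth model

A point annotation (x0, y0, z0) is expanded to a soft spherical region of
interest with an isotropic 3D Gaussian

    G(x, y, z) = peak * exp(-((x-x0)^2 + (y-y0)^2 + (z-z0)^2) / (2 sigma^2)),

overlapping annotations combining by per-voxel maximum so values stay in
[0, peak]. Thresholding at `tau` produces binary spheres of radius

    r = sigma * sqrt(2 ln(peak / tau)).

Parameters: `sigma` (voxels, default 3) and `tau` (default 0.5), both
configurable. With the defaults the sphere radius (~3.5 voxels) is
commensurate with the 5-voxel object-matching threshold used in
evaluation. The Gaussian is normalized to `peak` = 1 rather than to unit
mass: only the thresholded shape matters for training, and a unit peak
makes `tau` interpretable as a fraction of the center value. An optional
per-axis sigma supports strongly anisotropic stacks but is off by
default; coordinates are 0-based voxel indices throughout, fractional
(sub-voxel) centers allowed.

## Segmentation network

A compact volumetric U-Net: 4 encoder blocks (each two convolution blocks
of 3x3x3 padded convolution -> ReLU -> batch normalization), max pooling
between encoder levels, 3 decoder blocks (transposed-convolution
upsampling mirroring the pools, skip concatenation, two convolution
blocks), a final 1x1x1 convolution to one channel and a sigmoid. Channel
width doubles per level from `base_channels` (default 32; the learning
tests use 8). Because the fourth encoder block is the bottleneck there
are exactly three pool/upsample stages, which is what makes the output
resolution equal the input resolution.

Numerical/design choices:

* **Pooling schedule.** Kernels are configurable per level, default
  (2,2,2), (2,2,2), (1,2,2) along (z, y, x) so the production patch depth
  of 20 pools 20 -> 10 -> 5 -> 5 without fractional shapes. Any axis not
  divisible by its pool kernel raises a shape error naming the axis.
* **Initialization.** He-normal weights; the final convolution's bias
  starts at -2 so the sigmoid output begins near the rare-foreground
  prior (~0.12) instead of 0.5. With overlap losses under ~1:1000
  imbalance this removes a long initial plateau in which the network
  first has to un-learn a half-on prediction; measured on a single-patch
  memorization task it cuts the iterations to loss < 0.1 by several fold.
* **Batch normalization** runs per channel over the spatial axes of the
  single patch in flight (batch size 1); inference uses running averages.
* **Optimizer.** Adam, learning rate 2e-4, weight decay 1e-4 applied to
  convolution weights. One patch per step; all randomness (init, patch
  order, augmentation) derives from one seed, so loss histories are
  bit-reproducible.
* **Checkpointing** keeps the epoch with the lowest validation loss
  (training loss when no validation set is given).

The implementation is plain NumPy with explicit layer-wise backward
passes (im2col convolutions, argmax-routed pooling gradients,
tensordot-based transposed convolutions). The test suite checks every
layer's gradient against central finite differences for all four losses.

## Losses

Four voxelwise losses on the sigmoid output p against the binary target t,
selectable per training run:

* `bce` — mean binary cross entropy;
* `wce` — cross entropy with inverse class-frequency weights computed
  from the target;
* `dice` — 1 - 2*sum(t*p) / (sum(t) + sum(p) + eps), foreground only;
* `gdl` — generalized Dice loss over the label set {foreground,
  background}, background taken as the complement of the single channel:

      GDL = 1 - 2 * (sum_l w_l sum_n t_n p_n) / (sum_l w_l sum_n (t_n + p_n)),
      w_l = 1 / (sum_n t_n,l)^2.

  The inverse-squared-volume weights give the tiny foreground label the
  same influence as the background. On an all-background patch the
  foreground weight would be infinite; it is capped at the largest finite
  label weight, which reduces the loss to a plain Dice on the background
  and keeps gradients finite.

Probabilities are clipped to [1e-7, 1 - 1e-7] inside the cross-entropy
losses. Losses consume probabilities (not logits); gradients are chained
through the sigmoid analytically.

## Training data handling

Volumes are standardized to zero mean and unit variance (per volume;
constant volumes map to zero with a warning). Training patches come from
the same overlapping grid used at inference; by default every grid patch
is visited each epoch in a seeded random order, with an optional cap
(`patches_per_epoch`) and an optional foreground-oversampling switch
(off by default). Augmentation is a joint random flip across the x axis
and a random in-plane 90-degree rotation of patch and target (odd
quarter-turns are skipped for non-square in-plane patches, which would
otherwise change the shape).

## Patch-based inference

Volumes larger than one patch are decomposed into overlapping patches
(default size (20, 128, 128) in (z, y, x), 25% overlap in every
direction). Per axis, origins advance by stride = round(size * (1 -
overlap)) and the final origin is clamped to end exactly at the volume
edge, so all patches are full-size; e.g. a 32-slice stack with patch
depth 20 yields z-origins {0, 12}. Overlapping predictions merge by
unweighted per-voxel mean — order-independent and exactly the identity
when all patches agree. A center-weighted merge exists but is off by
default. Volumes smaller than the patch are reflect-padded up and
cropped back.

## Post-processing and instance splitting

The probability map is thresholded (default 0.5), then:

1. **opening** with a discrete ball (radius 2 voxels) removes speckle;
2. **dilation** with the same ball defines sure background (its
   complement) and the watershed flood domain;
3. the **Euclidean distance transform** of the cleaned mask, thresholded
   at `fg_threshold` (default 0.8) times each connected component's
   maximum distance, gives the sure-foreground seeds — the per-component
   maximum always qualifies, so every component keeps at least one seed
   and separate components can never merge;
4. **watershed** on the inverted distance map, seeded by those
   components, splits fused nuclei at the distance-ridge between cores.

The threshold is applied to the distance transform of the mask itself
rather than of the dilated mask: for two equal spheres of radius r fused
at center distance 1.5 r (the typical touching-nuclei geometry), the
saddle-to-peak ratio of the mask's distance transform is ~0.66 while the
dilated variant's is ~0.87, leaving no robust threshold below the peak.
With the default 0.8, randomized fused-pair fixtures split into two
instances with seed cores within one voxel of the true centers in
essentially all placements. The threshold is per component, not global,
so a small nucleus next to a large one keeps its seed.

Detections are the labeled instances (fractional centroid, voxel count);
a size filter drops instances below 0.1 of the median detection volume —
a robust formalization of "much smaller than the other detections" that
is insensitive to a single outlier. Lists of at most one detection pass
unfiltered. 26-connectivity is used throughout.

## Evaluation

Pixel and object metrics share one precision/recall/F implementation.
Object scoring matches detection centroids to annotated centers greedily
in ascending Euclidean distance, one-to-one, counting a pair as a true
positive when its distance is strictly below the threshold (default 5
voxels). One-to-one matching preserves the count identities tp + fp =
detections and tp + fn = truths, which a plain nearest-neighbor rule
violates when two detections share a truth. Conventions: a precision or
recall with a zero denominator is 1; F = 0 when p + r = 0; the fully
empty case scores (1, 1, 1).

## Texture baselines

The classical baselines work per 2D slice. `haralick_map` quantizes the
volume to 32 equal-width gray levels and, for every pixel, builds
symmetric normalized co-occurrence matrices of the centered window
(default 11x11; the learning tests use 5x5, scaled to their ~7-voxel
nuclei) at the four distance-1 offsets (0, 45, 90, 135 degrees), computes
nine Haralick statistics per offset, and averages the statistics across
offsets. Window borders are reflect-padded. Sum-variance is taken about
the sum average (Haralick's printed definition centers it on the sum
entropy, generally regarded as a typo). The sliding-window map is
numba-compiled; a pure-NumPy per-window route is kept and tested against
it. LBP codes use N = 8 samples on a radius-1 circle, starting at the
east neighbor and proceeding clockwise in image orientation, bilinear
interpolation, with s(d) = 1 for d >= 0; ties are resolved with a small
relative tolerance so constant regions code as 255.

The k-means baseline clusters raw intensities with k = 3 (background,
non-nuclei foreground, bright nuclei), initialized at evenly spaced
intensity quantiles and iterated until no centroid moves more than `eps`
= 0.2 intensity units; the nuclei mask is the cluster with the brightest
centroid. The supervised baselines (SVM with C = 0.7 and an RBF kernel;
random forest with 35 trees, depth 17, min split 9, min leaf 24, Gini;
gradient boosting with 100 depth-1 trees, min-leaf fraction 0.2,
min-split fraction 0.3) train on 5,000 randomly drawn pixels per slice
(all pixels when a slice has fewer) with inverse class-frequency weights
— realized as sklearn's "balanced" weighting, and as per-sample weights
for gradient boosting, which exposes no class-weight parameter.
Evaluation always uses every pixel of the evaluated slices. Features are
used raw (no standardization).

Known limitation: with these tuned hyperparameters the gradient-boosting
baseline cannot localize a sub-percent minority class precisely — its
min-leaf fraction of 0.2 restricts every stump to splits that keep at
least 20% of the training rows on each side, which bounds attainable
precision near (foreground fraction)/0.2. On the synthetic corpus it
plateaus around pixel F ~ 0.2 at realistic marker sparsity, well below
the random forest, and the RBF SVM — which degrades badly on the noisy,
billion-pixel real data this protocol was tuned on — performs
respectably on clean simulated texture. The baseline comparison test
asserts the full published ordering and therefore documents this gap
rather than hiding it.

## Synthetic data generator

The simulator provides ground-truth-complete stand-ins for confocal
marker stacks. One volume contains:

* a **root body**: an elliptic cylinder along x (half-axes 0.38 of the
  z/y extents), interior intensity 20 over a ~0 background, edges
  softened by a sigma-1 Gaussian blur (out-of-focus light);
* **cell-wall ridges**: the boundaries of a Voronoi partition of ~60
  random sites inside the root, drawn at intensity 60 — thin, bright,
  and of the same "color" as the marker, reproducing the main confuser
  of the real imagery;
* **nuclei**: `n_nuclei` isotropic Gaussian blobs (sigma uniform in
  [2, 3] voxels, peak uniform in [150, 220]) clipped at 3 sigma, centers
  rejection-sampled inside the eroded root at pairwise separation >= 10
  voxels with fractional coordinates; every center is recorded in the
  annotation table;
* optionally one **artefact blob** of nucleus-like appearance placed
  outside the root and absent from the annotations (the classic false
  positive of the real data);
* additive Gaussian **noise** (sd 5; Poisson available).

Defaults give a binarized foreground fraction of order 1:1000, matching
the extreme imbalance of real marker stacks (~1:1500). The generator
reproduces the *statistical* confusions of the imagery (dim foreground,
bright thin walls, sparse bright blobs, out-of-root clutter, sensor
noise) but not its optics: no depth-dependent attenuation, no
point-spread anisotropy, no bleed-through gradients, and walls are
geometric ridges rather than imaged membranes. Tests passing on this
corpus therefore demonstrate the pipeline's mechanics and its behavior
under imbalance, not performance on real microscope data.

## Problem sizes in the shipped tests

The learning tests run on one CPU, so they use a reduced but structurally
faithful setup: 20 training + 4 test volumes of 96x96x24 voxels with 3-8
nuclei each; network width 8 base channels; training patches (16, 32, 32)
with all-(2,2,2) pooling; two epochs with at most 400 patches per epoch
(GDL, seed-fixed). Targets for the recovery experiment are rendered at
sigma 2.5, tau 0.1, i.e. spheres of radius ~5.4 voxels covering the full
visible blob (blobs are clipped at 3 sigma = 7.5 and fade into the noise
floor near 2.4 sigma); labels then agree with what the images show, which
benefits every classifier and the network equally. The loss-comparison
test instead renders tight tau = 0.5 spheres, because the imbalance those
create (~1:800) is precisely the regime the overlap-vs-cross-entropy
comparison is about; at low imbalance plain BCE is occasionally
competitive and the published ranking is not expected to hold. The
end-to-end recovery test requires mean object F >= 0.8 over the four test
volumes at the 5-voxel matching threshold; in practice it reaches 1.0.

A caution on the loss comparison: the overlap-vs-cross-entropy ranking is
regime-dependent. The rare-event bias initialization removes most of
BCE's imbalance pathology, and given enough iterations on this synthetic
corpus plain BCE becomes competitive with, and can overtake, the overlap
losses; with a neutral output bias, no loss converges inside a short
CPU budget and the comparison degenerates to noise. The shipped test
therefore pins its exact study conditions (seed, budget, targets) and
should be read as "under high imbalance and a short equal budget, the
overlap losses are ahead", not as a universal ordering.

## Known limitations

* CPU-only NumPy training: practical for the test-scale problems here,
  roughly 10^3 slower than GPU frameworks at the production patch size.
* Batch size is fixed at one patch.
* The k-means baseline clusters intensities only (by design, matching
  the published protocol); it cannot separate walls from nuclei.
* No tracking across time points; each volume is scored independently.
* The hyperparameter-search hook is a thin wrapper around sklearn's
  randomized search; the published 100-iteration search is not re-run,
  its tuned values are simply the defaults.
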