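# Methods

`trenchroot` quantifies the root distribution of a field-grown plant
from photographs of a trench profile wall — the flushed vertical soil
face exposed beside the plant ("hill"). The pipeline has three stages:
geometric normalization of the photograph, semantic segmentation of
root pixels with a U-shaped convolutional network, and reduction of the
binary root map to centroid-quantile phenotypes. A seeded synthetic
image generator stands in for field photographs, so every stage is
testable with pixel-exact ground truth.

## The normalized frame

All analysis happens in a fixed frame: a 60 cm deep x 60 cm wide crop
of the wall at 25.6 px/cm (256 dots per 10 cm), i.e. a 1536 x 1536
raster with the soil surface on row 0 and the hill at a known column
(center by default). Raw photographs are mapped into this frame by a
counterclockwise rotation correction, a rescale derived from the
in-image scale bar, and a half-open crop window; the per-image geometry
is supplied manually in a sidecar CSV, and lens distortion is assumed
corrected upstream. Photographs are resampled bilinearly, label masks
with nearest-neighbor so they stay binary. A *test-scale* frame
(`TEST_FRAME`, 6.4 px/cm, 384 x 384) covers the same physical wall at
1/4 resolution; it tiles into the same 6 x 6 grid with 64-px tiles and
is what the test battery and desk experiments use.

## Segmentation

The segmenter is a U-shaped encoder-decoder with skip connections.
Three choices depart from the classic design: 3 x 3 convolutions are
zero-padded so tiles keep their size, batch normalization follows every
convolution and every up/down-sampling step, and the head is a
single-channel sigmoid map (one class, root vs. soil). The full-scale
preset has 4 levels and 64 base channels on 256-px tiles; the
test-scale preset (3 levels, 8 base channels, 64-px tiles) is the
configuration every experiment here actually trains.

The network is implemented directly in NumPy (im2col convolutions,
hand-written backward passes, Adam). That keeps the package
dependency-light and bit-reproducible on CPU: given a seed,
construction, training and prediction are exactly deterministic, and a
reloaded checkpoint predicts bit-identically.

Training: Adam at learning rate 0.001; one pass over all tile pairs per
epoch, each pair freshly augmented (flip, rotation +/-15 deg, scale
0.9-1.1, brightness 0.8-1.2x, gamma 0.7-1.4, saturation 0.8-1.2x; the
geometric part applied identically to image and mask). The loss is
binary cross-entropy by default; a soft-Dice loss is selectable. The
Dice coefficient, 2|T∩P|/(|T|+|P|), is tracked as the quality gauge and
reported micro-aggregated over all pixels (per-image values are a
logging detail; the aggregate is what the acceptance experiment
quotes). Batch size 4 (8 in the desk experiments) — the "inputs per
epoch" bookkeeping is independent of it. Binarization threshold 0.5,
strict inequality.

Whole images are predicted by splitting into the disjoint 6 x 6 tile
grid, a per-tile forward pass, and reassembly in row-major order. There
is no overlap or seam blending, so prediction is exactly equivariant to
translations by one tile stride — a property the tests exploit.

## Phenotypes

A binary root mask is folded in half about the hill column (left and
right combined by logical OR — the folded object is still an image),
thinned to 1-px centerlines (`skimage.morphology.skeletonize`), and
summarized by cumulative-length quantiles. One skeleton pixel
represents 1/25.6 cm ~ 0.39 mm of root length.

* **Depth50**: smallest depth d such that rows 0..d contain 50% of the
  total skeleton length. The per-row counts are cumulated, normalized,
  and the crossing bin is linearly interpolated; at 0.39 mm bins the
  interpolation choice is far below measurement noise.
* **Width50**: the same quantile along the distance-from-hill axis of
  the folded raster.

Folding before thinning matches the pipeline this package reimplements;
its cost is that roots overlapping after the fold merge under OR — a
documented limitation quantified below. Empty masks raise rather than
return zero phenotypes: an image with no detected roots is a failed
prediction, not a plant without roots.

## Synthetic trench generator

The generator emulates the features of the photographs that matter to
the pipeline, with exact truth:

* **Soil**: a brown base palette ("topsoil dark loam" or "subsoil
  red-brown"), multiplied by low-frequency correlated texture, a
  vertical illumination gradient, fine grain, and a per-image exposure
  factor in 0.8-1.2 emulating sunlight variation.
* **Roots**: each root starts near the hill point on row 0 (crown
  scatter up to 6 cm by default) and walks downward, drifting outward
  (0.5 px lateral step per row). Each root occupies exactly one pixel
  per row down to its maximum depth. Rendered strokes are 2-6 px wide,
  pale and desaturated, alpha-blended over the soil.
* **Labels**: the truth mask is the centerline raster dilated to a
  fixed 4-px pencil width regardless of rendered root width, with no
  anti-aliasing — the manual annotation convention.
* **Truth parameters** are computed from the exact 1-px centerline
  raster through the phenotyping math itself (fold + quantiles, no
  thinning needed), bypassing segmentation entirely.

Root maximum depths follow an exponential law censored at the frame
depth: a root survives past depth x with probability e^(-λx), so the
*pixel* depth distribution is exponential truncated to [0, 60 cm] and
Depth50 has the closed form -ln(1 - 0.5(1 - e^(-60λ)))/λ. Depths are
drawn by jittered stratification (one uniform per equal-probability
stratum), which shrinks the realized histogram's error from
O(1/sqrt(n)) to O(1/n); with 300 roots the generator's truth Depth50
sits within ~0.06 cm of the closed form. Two placement details keep the
law exact on the raster: no two pixels may share a (row,
distance-from-hill) slot (so the OR of the fold never destroys pixels),
and by default centerlines keep a 6-px minimum folded separation so
that dilated strokes rarely merge. Dense configurations (hundreds of
roots) should set `min_separation_px=0`, keeping slot exclusivity only.

Dataset generation emulates a variety panel: per-image depth-law rates
are log-spaced over 0.03-0.14 /cm (shuffled), spanning median rooting
depths of roughly 5-23 cm — the varietal range the phenotype is meant
to resolve.

**What the generator does not emulate**: stones, cracks, worm channels,
specular highlights, real root branching topology (roots are
independent walks), and real annotation noise. Passing tests therefore
demonstrate that the pipeline's geometry, training loop and estimators
are correct and well-calibrated on controllable imagery — not that the
shipped defaults reach field-grade accuracy on real photographs, which
requires training on real labeled data.

## Closing the loop, and its known bias

Phenotyping the 4-px label mask (fold, thin, quantiles) recovers the
centerline truth within 0.5 cm for sparse root systems (12 roots at
full scale). The residual is a small systematic shallow-shift of
roughly 0.2-0.4 cm: the pencil dilation extends stroke ends by ~2 px
and thinning erodes them differently, so the label mask carries
slightly more shallow length than the centerlines. The same mechanism
exists in real annotations ("pencil covers the root tip"); it cancels
in comparisons made on a common convention.

## Desk-scale experiments

`trenchroot.experiments` freezes the reference protocol:

* **Segmentation**: 10 training trenches at the test frame -> 360
  64-px tile pairs, 20 epochs, batch 8, BCE loss; validation on 12
  held-out trenches. Reported: micro Dice over validation pixels and
  the Pearson correlation between truth and predicted Depth50/Width50.
  Typical results: Dice ~0.9, r ~0.99. (Synthetic roots are easier to
  segment than field roots, which is why desk-scale Dice exceeds what
  field imagery yields.)
* **Heritability**: one-way random-effects decomposition over
  accessions; V_G = (MS_accession - MS_error)/r̄ with r̄ the harmonic
  mean of replicate counts (clipped at 0), V_P = V_G + MS_error,
  H² = V_G/V_P. Simulating 60 accessions x 3 replicates with V_G = 3,
  V_E = 1 (analytic H² = 0.75) over 200 draws recovers the mean within
  0.1. H² is invariant to affine rescaling of the trait.
* **ANOVA calibration**: a 7-group null (4 observations per group, one
  normal law) over 1000 draws rejects at α = 0.05 between 3% and 7% of
  the time — the validity check behind using a non-significant
  acquisition-date ANOVA as evidence of protocol robustness.
* **Steel-Dwass**: each pair of groups is midranked alone, the rank sum
  standardized with the tie-corrected variance, and sqrt(2)|z| referred
  to the studentized-range distribution with k groups and infinite
  degrees of freedom. At k = 2 this reduces to the two-sided
  normal-approximation rank-sum test; under a k = 4 null the
  family-wise error stays at or below ~0.05-0.07.
* **Clustering**: per-accession mean (Depth50, Width50) z-scored per
  trait, agglomerative clustering with nearest-neighbor (single)
  linkage, Euclidean distance, tree cut at k = 5 by default. "Neighbor
  method" is ambiguous; single linkage is the literal reading, complete
  linkage is available via the `method` argument. Single linkage chains
  smoothly varying panels into one large cluster plus outliers — that
  is a property of the method, not a bug.

## Numerical and design choices

* Coordinates are 0-based, row-major, (row = depth, col = width);
  crop windows are half-open.
* Quantiles use "smallest bin with cumulative >= q" plus within-bin
  linear interpolation.
* Dice of two empty masks is defined as 1 (perfect agreement on
  absence).
* Negative variance-component estimates clip to 0, so H² lies in [0,1].
* The binarization tie rule is strict (`prob > threshold`).
* Checkpoints are a single `.npz` archive holding weights, batch-norm
  running statistics, both configs, the training history and a format
  version.
* Seeds: every stochastic component takes an explicit seed;
  sub-seeds are derived with `numpy.random.SeedSequence` and stay
  below 2^31.

## Problem sizes

The shipped tests and the reporting script train only the test-scale
network on the 384-px frame (minutes on one CPU) and run the
statistical calibrations at 200-1000 draws. Full-scale presets
(256-px tiles, 4 levels, 64 base channels, 500 epochs) are provided and
functional but are meant for real datasets on serious hardware; nothing
in the desk-scale conclusions depends on them.

## Limitations

* Segmentation accuracy on real trench photographs is not established
  here; the synthetic domain is deliberately easier.
* The fold-then-thin order merges roots that overlap after folding;
  phenotypes of extremely dense root systems are biased by stroke
  merging (quantified above for the supported regimes).
* Per-root instance measures (diameter, branching) are out of scope;
  the skeleton length is the only size proxy.
* The heritability estimator assumes a balanced-ish one-way layout;
  no mixed-model (REML) or multi-environment decomposition is offered.
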