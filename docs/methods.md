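# Methods

## The probe

`pdprobe` measures how a black-box image regressor uses its input.  The
model under study maps a packed 299×299×3 integer image (intensities
0–254) to a scalar — in the motivating application, hand bone age in
months.  For a pixel p the partial derivative of the prediction f with
respect to the intensity at p is approximated by a forward finite
difference: all three channels of p are incremented by a step h
(default 1 intensity unit) and

    PD(p) = [ f(x + h·u_p) − f(x) ] / h ,

where u_p is the indicator of pixel p across the three channels.  The
unit of PD is months per intensity unit.  Repeating this over a pixel
region (typically the hand mask) yields the PD map.  Nothing about the
model is needed beyond a deterministic `predict`; the contract requires
the model to accept intensities up to 255, because a 254-valued pixel
plus the unit step reaches 255 and is deliberately passed through
unclamped.

Forward differencing is exact for affine models.  For a twice-
differentiable model with |d²f/dt² along u_p| ≤ B, the approximation
error is bounded by h·B/2.  A central-difference mode
([f(x+h·u)−f(x−h·u)]/2h) is available behind a flag but off by default:
the single-sided probe is the reference behaviour, and at the 0–254
scale a downward step at a zero pixel would leave the valid range.

The baseline prediction f(x) is computed once per map and reused; under
the determinism contract this is indistinguishable from recomputing it
per pixel.  Batched probing (`batch_pd_map`) exists as an engineering
affordance for models with vectorized inference; its batch predictions
are defined to apply `predict` per image, so batched and sequential
maps are bit-identical by construction rather than by accident of BLAS
summation order.

## Surrogate oracles and the dyadic-weight design

Because real trained networks are not required (or reproducible at desk
scale), validation runs against closed-form surrogates:

- **constant** — f = c.  Zero gradient; the probe must return exactly 0.
- **linear** — f = Σ w·x + b, weights uniform on ±1e-4.  The difference
  quotient equals the channel-summed weight exactly, for any step.
- **quadratic** — f = Σ a·x², coefficients uniform on ±1e-6.  Exposes
  the forward-difference bias: PD(p) = Σ_ch a(2x+1), against the true
  derivative Σ_ch 2ax.
- **radial-bump** — f = A·exp(−(v−1)²/2) with v a normalized Gaussian-
  weighted pixel sum.  Smooth and bounded, with certified curvature
  bound B = A·(3c_max/s0)² along the probe direction (max |h''| = 1 for
  the Gaussian); used to check the h·B/2 error bound.
- **regional-sum** — a linear form piecewise constant on a label map;
  its PD map is a step function over the ROIs.

A deliberate numerical choice: drawn weights are quantized to dyadic
rationals — multiples of 2⁻⁴⁰ for linear-family weights, 2⁻³⁰ for
quadratic coefficients.  With integer intensities ≤ 255 every product
w·x is then exactly representable in float64, and every partial sum of
the dot product stays below 2⁵³ quanta, so the dot product is exact
regardless of summation order and the probe's difference quotient
carries **zero** floating-point error.  This is what lets the
linear-oracle tests demand literal equality rather than a tolerance.
The magnitudes (weights ±1e-4) keep per-pixel PDs in the display decade
the overlay defaults are tuned for.

## Image preparation

The chain mirrors the standard preparation of hand radiographs for a
299×299×3 regressor:

1. **Background subtraction** — a scalar level (default: the 1st
   percentile of the frame; a fixed value may be supplied), clipped at
   zero.
2. **Hand mask** — intensity threshold (default Otsu; fixed-value
   override), then a morphological opening (erode→dilate) with a disk
   of radius 5 at the 598-pixel scale to delete isolated bright
   islands, then retention of the largest connected component.  For
   nonuniform backgrounds a user-traced mask file bypasses generation.
3. **Masking** — intensities outside the hand are set exactly to zero.
4. **Square crop + resize** — the mask bounding box, expanded by a
   configurable margin fraction and squared about its centre
   (zero-padded where it leaves the frame), bilinearly resized to
   598×598.  The mask rides through the identical transform and is
   re-binarized at 0.5; label maps use nearest-neighbour resampling.
5. **Cell packing** — each 2×2 cell becomes one 3-channel pixel:
   bottom-left → channel 1, bottom-right → channel 2, top-row mean →
   channel 3.  Within the bottom row the left-to-right order is a fixed
   convention; it cannot affect the probe, which always perturbs all
   three channels together.
6. **Intensity scaling** — affine map of the frame's [min, max] to
   [0, 254], rounded half-up to unsigned bytes.  Scaling is computed
   over the whole frame; after masking the background is zero, so the
   minimum is zero whenever any background is visible.

Hand orientation (upright left hand, palm down) is the caller's
responsibility — only a horizontal-flip flag is offered, since
orientation normalization is a manual curation step, not an algorithm.

The 598-scale mask is reduced to the 299 model grid by 2×2-cell
majority vote, ties counting as inside (the least biased fixed rule).
Labels reduce by per-cell nonzero majority requiring at least two of
four pixels, ties toward the smaller label; reduced labels are then
clipped to the reduced mask.

## ROI statistics and trends

Per image and ROI the statistic is the **mean APD**: the arithmetic
mean of |PD| over the ROI's computed pixels.  Labeled pixels that lost
their PD to the mask reduction are excluded and the count logged.  Each
ROI's mean APD is divided by the sum of the mean APDs of ROIs 1–4 of
the same image, giving the **relative mean APD**; ROI 5 (the thumb-web
muscle region, which carries no skeletal-maturity information) shares
the same denominator so its values sit on the same scale.  By
construction the ROI 1–4 relative values sum to 1 per image.
Multiplying a PD map by k > 0 scales every mean APD by k and leaves
every relative value unchanged.

Cohort trends are unweighted ordinary least squares of relative mean
APD against reference age in months, with the classical two-sided
t-test on the slope (no weighting, no robust alternatives, no
multiple-testing correction across ROIs — each ROI is reported on its
own).  Cohort descriptive tables use the sample SD (n−1 denominator).

## Overlay rendering

PD values span decades, so display scores are tanh(pd/T): odd, strictly
monotone, saturating at ±1 so that ±∞ land on the two colormap
extremes, with the printed threshold T as the curve's natural scale.
Defaults: T = 4e-3 months per intensity unit inside the mask and 4e-2
outside (outside-mask PDs run an order of magnitude larger); a
diverging blue–red map with neutral midpoint; opacity 0.5.  A hard
clamp at ±T is available behind a flag for callers who prefer linear
coloring up to saturation.  Pixels without a computed PD always show
pure anatomy.  Note that in double precision tanh reaches exactly ±1
once |pd/T| exceeds ~19; strict monotonicity of rendered scores holds
on the pre-saturation range.

## The phantom generator

Phantoms are geometric hand stand-ins, not photorealistic radiographs:
a palm ellipse, four finger capsules, a slanted thumb capsule and a
wrist block, rendered bright (tissue level 80 over background 10) on a
598×598 frame with small seeded jitter of the geometry.  The stored
ground-truth mask is the silhouette *after* the same disk-5 opening the
mask generator applies — convex corners of an ideal silhouette are not
invariant under opening, so baking the opening in is what makes exact
mask recovery on a clean phantom a meaningful test.  Optional bright
background islands (for cleanup tests) are placed in the top margin
band, far from the hand; Gaussian noise (default SD 2) is added last.

ROI labels follow the anatomical roles: 1 a wrist band, 2 five
mutually disconnected mid-metacarpal patches, 3 five metacarpal-
phalanx joint patches, 4 the fingers and distal thumb, 5 a small
thumb-web disk — always the smallest ROI, and the five ROIs never tile
the whole mask.  Declared per-ROI pixel counts are recounted from the
emitted label map.

The age parameter (15–216 months, the emulated test range; cohort ages
drawn uniformly by default) drives bone-like bright cores laid along
metacarpal and phalanx axes with Gaussian cross-sections whose
amplitude (50 + 0.45·age) and width both increase strictly and
continuously with age, so mean core intensity in ROI 2 is strictly
monotone in age at fixed seed.  What the phantom does *not* model:
ossification centres, growth-plate fusion, carpal-bone count, soft-
tissue texture, scatter, or any radiographic physics.  Tests passing on
phantoms therefore validate the *pipeline machinery* — masking,
packing, probing, ROI bookkeeping, statistics — not any claim about
real radiographs or a real trained model.

## Problem sizes and runtimes

A full in-mask map at the 299 grid probes ~30k pixels, i.e. ~30k
`predict` calls (a few seconds for the analytic surrogates; a real
network costs whatever its inference costs — historically ~13 minutes
per radiograph for a GPU-hosted CNN).  The shipped validation suite
uses one full-mask map, a 32×32 curvature patch, three label-region
maps for batch equivalence, a 20-phantom cohort for normalization
conservation, 500+200 replicates for slope recovery/power, and a
5-phantom cohort for the end-to-end determinism check.

## Degenerate inputs and tie-breaks

Constant images cannot be thresholded or rescaled (errors); empty masks
and empty probe regions are errors; a model returning non-finite
predictions aborts the map; per-image pipeline failures are logged,
recorded in the manifest and skipped, and a run fails only when every
image fails.  Rounding is half-up in intensity scaling and rendering;
mask re-binarization after resize is at ≥ 0.5; majority reductions
break ties as stated above.  PD CSVs store floats at 17 significant
digits so reruns and resumed runs are bit-identical.

## Known limitations

- Automatic masking assumes a uniform background; nonuniform
  backgrounds need a user-supplied mask.
- ROI label maps for real radiographs must be drawn externally; only
  phantoms get programmatic labels.
- The probe costs one model evaluation per pixel; there is no
  lower-cost approximation and none is planned (backprop-based
  gradients are out of scope by design — the point is to need nothing
  but `predict`).
- Stochastic models must be wrapped into deterministic form by the
  caller; the toolkit does not average repeated predictions.
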