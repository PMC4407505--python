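# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Feature extraction

**Color.** Images are converted RGB → HSV (hexcone model, channels on
[0, 1]); each channel's arithmetic mean and population SD (divide-by-N)
are the six color features. Hue is treated as a *linear* variable, not a
circular one: the mean of a half-red/half-cyan image is 0.5, not 0. This
matches stock HSV channel statistics and keeps the features trivially
interpretable; it is inaccurate for scenes whose hues straddle the red
wrap-around point. A config flag switches to sample SDs.

**Entropy.** Shannon entropy (bits) of the 256-bin histogram of the
grayscale image (ITU-R BT.601 luma weights, rounded). 0 log 0 := 0. The
value is 0 iff one bin is occupied and 8 iff all bins are equal.

**Weighted Canny edges.** Gradients are derivative-of-Gaussian filters
(σ = 1.4, `nearest` boundary handling); non-maximum suppression compares
each pixel against its two neighbors along the quantized gradient
direction, with a strict inequality on the forward neighbor so plateau
ridges stay one pixel wide; hysteresis linking uses the standard
weak/strong scheme. The base threshold pair is chosen per image: the high
threshold is the 0.70 quantile of the nonzero gradient magnitudes and the
low threshold is 0.4 × high. This heuristic is an approximation chosen for
transparency — the reference environment's stock heuristic is not
published — so absolute ED values are implementation-relative; analyses
only consume comparisons across images processed identically. The detector
runs twice, with both thresholds scaled by 0.8 (high sensitivity) and by
1.6 (low sensitivity). Detection at low sensitivity ⇒ detection at high
sensitivity (threshold nesting), so the weight map {0, 0.5, 1} is well
defined: 1 = salient (found at both), 0.5 = faint (found only at high
sensitivity). ED = Σ weights / (H·W). A constant image returns an all-zero
edge map rather than an error.

**Straight edges.** Edge pixels are assigned to one of eight orientation
bins by tan⁻¹(G_y/G_x) folded to [0°, 180°), with bins *centered* on 0°,
22.5°, …, so cardinal and diagonal orientations fall mid-bin instead of on
a bin boundary (otherwise orientation noise fragments exactly-vertical
edges between two bins). Before labeling, the edge mask is topologically
thinned to one-pixel traces: step edges and diagonal ridges otherwise
yield two-strand staircases whose perpendicular variance fails any strict
straightness test. Within each bin, 8-connected components of at least 10
pixels are tested (smaller fragments are degenerately collinear and are
never classified straight); a component is straight when the singular
values s₁ ≥ s₂ of its mean-centered coordinate matrix satisfy s₂ = 0 or
(s₁/s₂)² > 10⁴ — i.e. an eigenvalue (variance) ratio of 10⁴, equivalently
s₁/s₂ > 100. The variance reading was chosen over the literal
singular-value reading because the latter rejects every rasterized
oblique line; the threshold is exposed in `StraightConfig`.

Consequences of the strict 10⁴ criterion worth knowing:

- A rasterized line at an arbitrary angle carries Bresenham staircase
  jitter of variance up to 1/12 px², so it passes only above roughly 100
  px length. At 0°, 45°, 90°, 135° the raster is exactly collinear and
  passes at any tested length.
- Large rasterized circles have exactly collinear flat runs at their
  cardinal tangent points; runs of ≥ 10 px are (correctly) straight.

SED counts straight-edge *pixels* (unweighted) per image pixel; after
thinning, edge pixels 8-adjacent to a straight trace are recaptured into
the straight mask so the densities refer to the full detected edge. DER
uses the faint/salient weights in both numerator and denominator:
DER = 1 − (straight edge weight)/(total edge weight). DER is undefined
(reported as missing) when ED = 0.

## Synthetic scenes

`generate_scene` renders an HSV canvas — per-pixel uniform hue jitter, a
vertical saturation gradient, Gaussian brightness texture — and draws
3-px-thick straight segments (≥ 40 px) and circular contours at a
brightness contrast of ±0.35. Line orientations default to the four
canonical angles, where rasterized segments are exactly collinear and the
straightness criterion certifies them at the 96×128 default scene size;
`orientation_mode="free"` draws arbitrary angles, which the strict
criterion only certifies for long segments. Curves are circles with
radius ≥ 12, whose per-bin arcs stay far from the straightness threshold.
The scene gradient used by the pipeline demo runs from bluish-gray,
uniformly saturated line grids (built end) to yellow-green, desaturated
but saturation-diverse curved fields (natural end), consistent in sign
with the reference naturalness model. What these scenes do *not* emulate:
photographic texture, occlusion, perspective, lighting, and long oblique
building edges; junction fragmentation also leaves a DER floor of ~0.2–0.4
for pure line grids at this scale, so tests assert orderings
(nature > urban in DER, < in SED), not the idealized 0/1 endpoints.

## Rating and reaction-time simulators

`simulate_ratings` generates, per participant × image,

- naturalness = β₀ + Σ βᵢ featureᵢ + ε, with the reference estimates
  (intercept 3.573, ED 0.717, Sat −0.756, …) as default coefficients and
  rating noise SD 0.9;
- preference = 4 + Σ bᵢ z(featureᵢ) + ε with the standardized reference
  betas (SED −0.382, SDsat 0.214, …) and noise SD 0.8;
- RT = 1.5 s − 0.25 · (modeled naturalness, centered) + ε, noise SD 0.3 s,
  floored at 0.2 s. The RT scale parameters are the package's own choices
  (no reference distribution exists); the negative slope produces the
  faster-judgment-for-bottom-up-nature coupling.

Ratings are continuous by default; Likert rounding/clipping to {1..7} is
an option, off by default because the analyses consume participant means,
which are near-continuous, and rounding biases parameter recovery.
Because rating noise is independent across raters, image-mean ratings have
noise SD σ/√n_raters, and the residual ("non-modeled") naturalness at the
image level is pure noise: unlike real data, it carries no semantic signal
and hence no information about preference. Demo-scale classification
accuracies for predictor sets involving non-modeled naturalness are
therefore not comparable to real-data values — a deliberate limitation of
the generating model, which contains no latent semantic variable.

`simulate_interaction_dataset` draws modeled naturalness, non-modeled
naturalness and RT as independent standard normals and generates
preference = b₁·mod + b₂·RT + b₃·RT·mod + b₄·nonmod + b₅·RT·nonmod + ε.
Defaults b = (0.453, −0.036, −0.247, 0.482, 0.108) follow the reference
moderation models; since those are two separate fitted models with
different RT main effects (−0.036 vs 0.069), the joint generator carries
the modeled-model value. Noise SD defaults to 0.7, which puts the total
variance of preference near 1 so that re-standardization in the fitting
step does not rescale the coefficients. Feature tables without images are
sampled from independent uniforms over documented per-feature ranges
(e.g. ED ∈ [0.02, 0.30], entropy ∈ [4.0, 7.9]); a correlation structure is
deliberately not imposed — recovery tests need identifiable, well-
conditioned designs.

## Aggregation and order checks

RTs are z-scored within participant (sample SD; error on zero variance)
before averaging, so between-participant speed differences cancel.
Per-image means are taken over available raters. The counterbalance check
is a per-image two-sample t-test between the two task-order groups —
Welch by default, pooled-variance optional; groups are compared in sorted
label order. The reported quantity is the minimum p across images, to be
judged against the number of simultaneous tests.

## Regression engine and decomposition

OLS runs through a QR-based solver with an intercept always in the
design. Standardized fits z-score X and y (sample SD) first and do not
report the intercept, which is exactly 0; keeping it in the design leaves
the residual degrees of freedom at n − k − 1, matching the convention of
the reference tables. Confidence intervals use the exact t critical
value. Rank-deficient designs raise an error naming the collinear
columns. The naturalness split stores fitted values and residuals of the
10-feature fit (so modeled + non-modeled ≡ observed, exactly) plus
color-only (6-feature) and structure-only (4-feature) sub-model
predictions. Moderation models z-score preference, the component and RT
across images and form the product *after* z-scoring, without
re-standardizing it — the convention under which simple slopes at RT
z-levels ℓ ∈ {−1.5, 0, +1.5} are exactly b_component + ℓ·b_interaction.
RT levels refer to the SD of z-scored mean RTs across images.
`r2_from_f` converts a printed F(k, df₂) back to R² = kF/(kF + df₂) and
adjusted R² for consistency checks; the reference preference model's
F = 14.41 implies adjusted R² 0.305, a 2-dp rounding tension (0.30 vs a
printed 0.31) the function surfaces rather than resolves.

## Classification

The median split labels values above the median high and below low;
values exactly at the median alternate into the smaller class (low first
on a dead heat), so 307 items split 153/154. The QD classifier fits one
Gaussian per class with unbiased (ddof = 1) covariances and empirical
priors; posteriors come from log-density differences via Cholesky
factors. Pairwise leave-one-out holds out every (high, low) pair, trains
on the remaining n − 2, and classifies both; the implementation downdates
per-class sufficient statistics (the held-out high image affects only the
high-class Gaussian), after centering the data once for conditioning, and
is tested to be numerically identical to refitting from scratch per pair.
Classification ties go to the high class in both code paths. Accuracy
averages per pair (each pair contributes 0, ½ or 1); per-image tallies
are also exposed because the per-pair/per-occurrence choice is a genuine
ambiguity. Backward elimination greedily drops the feature whose removal
yields the highest cross-validated accuracy (ties: drop the later-listed
feature) and stops when no removal strictly improves; subsets whose
covariances are singular score as unusable rather than erroring.

## Problem sizes and calibration replicates

Defaults were chosen so the full suite runs in well under a minute of
compute per module: recovery tests use 2,000–5,000 simulated images;
coverage checks use 40–60 replicates; the order-effect null calibration
uses 1,500 simulated images (300 through the package path); the
permutation chance check uses 200 images × 20 permutations. These sizes
give the assertions comfortable margins (binomial/coverage bounds) while
keeping the suite fast; they are the package's standing choices, not
tuned quantities.

## Known limitations

- The Canny base-threshold heuristic is a stand-in; absolute ED/SED/DER
  values differ from other implementations on the same images.
- The straightness criterion is harsh on short oblique lines (see above);
  real long building edges are less affected at photographic resolutions.
- Hue statistics are non-circular.
- The rating generator has no latent semantic component and no
  rater-specific biases; tests on it validate the estimators, not claims
  about human raters.
- Only two-class QD is implemented; priors are empirical, which after a
  median split are near-equal by construction.
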