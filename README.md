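# scenestats

Why do people prefer looking at natural scenes over built ones? One
candidate explanation is bottom-up: natural environments carry low-level
visual regularities — curved, fragmented edges, yellow-green hues, diverse
saturation — that the visual system picks up quickly, before any semantic
recognition of "nature". `scenestats` implements an analysis pipeline for
testing that idea with scene images and Likert ratings: it decomposes
images into ten low-level statistics, splits perceived naturalness into a
feature-predictable and a residual component, asks whether each component
predicts esthetic preference more strongly in fast or slow judgments, and
validates the regressions with a quadratic-discriminant classifier.

It is aimed at researchers in visual esthetics and environmental
psychology who want a reproducible, fully synthetic-testable version of
this analysis chain.

## The measures and models

For an RGB image, ten features are computed:

- **Color** (HSV, each channel on [0, 1]): mean and population SD of hue,
  saturation and brightness — `Hue, SDhue, Sat, SDsat, Bright, SDbright`.
- **Entropy**: Shannon entropy of the 256-bin grayscale histogram,
  `H = −Σ pₙ log₂ pₙ` (bits, max 8).
- **Edge density (ED)**: a Canny detector is run at two sensitivities
  (thresholds scaled ×0.8 and ×1.6 around a per-image base pair); pixels
  found at low sensitivity weigh 1 (salient), pixels found only at high
  sensitivity weigh 0.5 (faint); ED is the total weight per pixel.
- **Straight edge density (SED)**: edge pixels are binned into 8 gradient
  orientations; 8-connected components whose coordinate-covariance
  eigenvalue ratio exceeds 10⁴ (singular-value ratio 100) count as
  straight; SED is straight pixels per pixel.
- **Disorganized edge ratio (DER)**: the share of edge weight *not* on
  straight edges — high in curved, fragmented (natural) scenes.

Per-image mean ratings (1–7 Likert) are then modeled by OLS:

    naturalness = β₀ + Σᵢ βᵢ·featureᵢ + e

The fitted value is **modeled naturalness** (the bottom-up component), the
residual **non-modeled naturalness**. Preference is regressed on each
component, reaction time (z-scored within raters), and their product; the
interaction's simple slopes at RT = mean ± 1.5 SD show whether a component
matters more in fast or slow judgments. Finally a quadratic discriminant
classifier (per-class Gaussians, unequal covariances) predicts
high-vs-low median-split preference under pairwise leave-one-out
cross-validation: each (high, low) image pair is held out, the model is
trained on the rest, and accuracy is averaged over all pairs (chance 50%).

Because the pipeline is exercised on synthetic data, the package also
ships first-class generators: parametric scenes with controllable
straight/curved edge content and HSV composition, and rating simulators
whose generating equations are the reference regression estimates, so
every stage can be checked by parameter recovery.

## Worked example

Run the numbered analysis scripts in order (they write to `results/`):

```
python analysis/01_generate_stimuli.py --seed 0
python analysis/02_simulate_ratings.py --seed 0
python analysis/03_aggregate_ratings.py
python analysis/04_naturalness_decomposition.py
python analysis/05_preference_models.py
python analysis/06_classification.py
```

With the default 80 scenes × 20 simulated raters this prints, among other
lines:

```
naturalness ~ 10 features: R2 = 0.572 (adj 0.510), F(10,69) = 9.21
preference ~ naturalness: slope = 2.791, R2 = 0.476
preference ~ modeled x RT: main +0.853, interaction -0.064; slopes fast/mean/slow = +0.950/+0.853/+0.757
  features               pairwise-LOO accuracy  94.2%
```

Reading: the ten features capture about 57% of the variance in simulated
naturalness ratings; more natural-looking images are preferred; and the
negative RT × modeled-naturalness interaction means the feature-driven
component of naturalness predicts preference best when judgments are fast
— the bottom-up signature the pipeline is designed to detect. The
classifier separates preferred from non-preferred scenes far above the 50%
chance level on these low-noise synthetic data.

The same stages are available as one command (`scenestats run-all
--out-dir run`) or individually (`scenestats extract | simulate |
aggregate | analyze | classify`); identical config and seed reproduce
byte-identical outputs, recorded in a manifest.

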