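# Methods

## The model

The detector is a pixel classifier plus a shape-free target extractor.
Every pixel of an RGB image (values in [0, 1]) is summarized by the mean
over its 7×7 neighborhood of up to six scalar color components: hue *H*
from the HSI model, chroma-blue *Cb* from YCbCr, the yellow–blue axis *b\**
from CIELab, and the raw *R*, *G*, *B* channels. The transforms are
implemented exactly as the classical closed forms:

- *H*: θ = arccos{½[(R−G)+(R−B)] / √[(R−G)² + (R−B)(G−B)]}, H = θ if
  B ≤ G else 360° − θ, divided by 360. The arccos argument is clamped to
  [−1, 1]; achromatic pixels (R = G = B, a 0/0 form) return 0 by
  convention — any constant would serve, since such pixels carry no hue
  information.
- *Cb*: (−0.1687 R − 0.3313 G + 0.5 B) + 128 on the 0–255 scale, clipped
  and divided by 255. The coefficients cancel exactly on grays (128/255).
- *b\**: [X Y Z] = (1/0.17697)·M·[R G B] with the classical CIE RGB
  matrix, then b\* = 200[f(Y) − f(Z/1.192)], f(t) = t^⅓ for t > 0.008856
  else 7.787 t + 0.138. There is no canonical [0, 1] scale for this
  quantity; we map it by the fixed affine (b\* + 128)/255 and clip. The
  constants are module attributes (`BSTAR_LO`, `BSTAR_HI`); the contract
  that matters is internal consistency — thresholds are learned on the
  same scale on which inference evaluates the plane.

Weak classifiers are linear rules on these features: thresholds on a
single component (grape on the high side for *H* and *Cb*, the low side
for *b\**) and a two-channel line a·v₁ + b·v₂ + c (default channel pair
B and R; the pair is configurable). The decision rule is h(x) = +1 iff
the signed margin is ≥ 0 — the boundary classifies as grape.

### LCE training

Parameters are found by lowest-classification-error search, generalized
to weighted samples so the same trainer serves inside the boosting loop
(uniform weights reduce to the plain error rate). For thresholds the
search is exact, not a grid: the weighted 0–1 loss can only change at
sample values, so candidate thresholds are the midpoints between
consecutive distinct sorted values plus two sentinels beyond the extremes
(the constant classifiers), evaluated in O(n log n) by prefix sums. Ties
are broken toward the candidate with the widest gap to the nearest sample
(a max-margin tie rule, for determinism and robustness); sentinel
candidates only win when strictly better than every interior one. The
threshold-below search reuses the same routine on negated values, which
preserves the boundary convention exactly. The line search scans 180
directions over the half-circle (both orientations), projecting samples
onto each direction and optimizing the intercept exactly by the 1-D
search — exact in the intercept, dense in angle, with the angular
resolution configurable.

### Boosting

Standard discrete AdaBoost over the pool of four weak-model families.
Per round, every available family is re-fitted under the current sample
distribution; the lowest weighted error ε_t wins and receives
α_t = ½ ln((1 − ε_t)/ε_t) (natural logarithm). Weights are multiplied by
e^{−α_t} (correct) or e^{+α_t} (misclassified) and renormalized to sum
to one — the only reading of the update under which the weights remain a
distribution. The strong classifier is the sign of the weighted vote,
with an exact-zero score classified as background (the sign rule is a
strict inequality).

Numerical and stopping choices:

- ε_t ≥ 0.5 ends training (the round is discarded); if that happens on
  the first round, training fails loudly ("no weak learner better than
  chance"). ε_t = 0.5 exactly would give α = 0, a useless round, and is
  rejected with the rest.
- A perfect weak learner (ε_t = 0) would get infinite weight; ε is
  floored at 1/(2N) — the standard smoothing — implemented as
  α(max(ε, 1/(2N))), which is monotone and equals the cap at ε = 0.
- Default `without_replacement=True`: each family is selected at most
  once, giving the one-round-per-family structure of a small fixed pool;
  a flag restores classical with-replacement boosting. A `frozen_pool`
  option weights fixed, pre-specified models without re-fitting.
- Training also stops when the strong classifier's unweighted training
  error drops below `target_error` (default 0.05) or at `max_rounds`
  (default: pool size; hard cap 5000).

The training loop is exposed both functionally (`boost.train`) and as a
model/results pair (`GrapeBoost` → `GrapeBoostResults`) with a per-round
summary table, prediction and scoring helpers, JSON persistence, and the
detection chain hanging off the results object.

## Segmentation and target extraction

Inference slides the 7×7 window over every pixel (reflective padding at
borders rather than shrinking the output) and thresholds the vote score.
The raw mask is cleaned in three steps, in order: connected components
smaller than a fraction (default 1/10, configurable — a stricter 1/4
variant is sometimes used) of the largest component are dropped, the mask
is opened then closed with a Euclidean disc {(dx,dy): dx²+dy² ≤ r²} of
radius 5, and background regions not connected to the image border are
filled. Connectivity is 8 by default (berry contacts are often diagonal).

Each surviving region becomes a detection marked by its tightest
axis-aligned bounding box. A region whose box is clearly landscape
(width/height > 1.4) is taken to be two clusters adhering side by side —
single hanging clusters are taller than wide — and is split by the
vertical line through its barycenter, pixels on the centroid column going
to the right part. The trigger and its threshold are this package's
heuristic choice: no principled criterion exists for deciding from a
silhouette alone that a region holds two clusters, and the threshold is
config-exposed. Splitting three or more overlapping clusters is out of
scope. Coordinates are 0-based (row, col) with half-open boxes
internally; reports can emit 1-based inclusive boxes.

## Evaluation metrics

`metrics` implements the method's protocol: overall two-class sample
accuracy; PRA = |manual ∩ algorithm| / |manual| × 100 per cluster (75%
is the usability bar for robotic harvesting); and detection rates
TPR = correct/total, FNR = spurious/(spurious + correct),
FPR = missed/total. The last two names are nonstandard (a
false-discovery-style rate and a miss rate respectively); the
implementation follows the defining formulas and the docstrings warn
about the naming. Display rounding is half-up to 2 decimals; raw values
are carried at full precision.

## The synthetic fixture generator

No public dataset accompanies the method, so `synth` emulates its data:

- **Pixel samples.** Each sample is one 7×7 window: a base color drawn
  from the class Gaussian in RGB (grape: dark purple, mean
  (0.26, 0.10, 0.30), σ = 0.07; backgrounds: leaf green, branch brown,
  sky, soil, σ = 0.08, mixed 50/12/23/15 to mirror scene composition),
  per-pixel jitter (σ = 0.04), an illumination transform, then the
  window mean of every component. Defaults are 400 grape / 800
  background training windows. The spreads were chosen once so that each
  weak family is individually informative but none is close to perfect —
  single-family error rates land in the ~6–30% band, the regime in which
  boosting has something to contribute — and are not tuned per test.
- **Illumination regimes** are affine gain/offset transforms
  (frontlight 1.15/+0.03, overshadow 0.72/−0.03, overcast 0.95/0) plus
  sparse specular highlight pixels, drawn 60/60/80 in mixed sampling.
  They stress classifier robustness to global intensity shifts; they do
  not model directional shading, colored light or shadows.
- **Scenes** are 300×400 images: a leaf wall with low-frequency lighting
  variation, a sky band, a soil band and a few branch strips, plus
  clusters rendered as ~100 overlapping berry discs (radius 6–9 px)
  inside a vertical ellipse (semi-axes 32×48 px). Berry colors are
  independent draws from the grape Gaussian, matching how training
  windows are cropped from many berries. The ground-truth mask is the
  exact union of berry discs. An `adjoining` preset renders two squatter
  clusters touching side by side, so the merged region's box ratio
  reliably exceeds the 1.4 split threshold. Optional pepper noise adds
  small grape-colored specks (radius 1–3 px) away from true clusters to
  exercise the cleanup chain.

Everything is deterministic under its seed, and suites written to disk
carry SHA-256 hashes in their manifest so regeneration is verifiable.

What passing the synthetic end-to-end test shows — and what it does not:
the full chain (train on generated windows, detect on generated scenes
across all three regimes, 20 seeds) recovers the true cluster count in
≥ 90% of scenes with mean per-cluster PRA ≥ 85%, and pepper noise never
survives cleanup. This validates the machinery: the LCE/boosting
training, the sliding-window classifier, and the denoising geometry.
It does not certify field performance: real vineyards have occlusion by
leaves, unripe berries inside ripe clusters, specular and shadow
structure, and color drift between cultivars, none of which the Gaussian
color model reproduces. Scene size (300×400 rather than the method's
600×800 working resolution) was chosen to keep the suite fast; cluster
geometry is scaled accordingly, and PRA is mildly sensitive to that
scale because boundary erosion by the 7×7 window and the radius-5 disc
is proportionally larger on smaller clusters.

## Known limitations

- The detector is purely color-based: anything berry-colored and large
  enough is a cluster. Texture/shape verification is out of scope.
- The adjoining-pair trigger is a heuristic; a genuinely wide single
  cluster will be split incorrectly, and vertically adhering clusters
  will not be split at all.
- The b\* normalization constants are a convention; models serialized
  with one convention must be evaluated under the same one (the JSON
  model files carry only component names and parameters, so changing the
  module constants invalidates saved thresholds on b\*).
- The achromatic-hue convention (H = 0) maps gray pixels to the red end
  of the hue axis; with a hue threshold around 0.65 this is harmless
  (they classify as background), but a model with a very low hue
  threshold would misread grays.
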