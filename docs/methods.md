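# Methods

This note documents the models, conventions and design choices behind
`dermseg`, in the spirit of a statistical software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Segmentation model

A dermoscopic image is treated as a two-class scene: a pigmented lesion,
darker and more textured, on lighter background skin. All frameworks share
one pipeline:

1. split the RGB image into channels;
2. optionally replace each channel by a wavelet feature image;
3. cluster the per-pixel feature values of each channel;
4. convert cluster memberships to a continuous lesion score in [0, 1];
5. resample channel scores to the image grid by nearest-neighbor
   interpolation (half-pixel-center convention) and fuse them by averaging
   R with G, then the result with B;
6. threshold the fused score (default 0.5) for the binary mask.

The fused score, not the mask, is the classifier output: evaluation sweeps
the threshold to build ROC curves, so every method must expose a continuous
score. This is why channel fusion operates on membership scores rather than
on label maps — averaging labels has no meaning, and label-level fusion
would collapse the ROC sweep to a single point.

**Lesion identification.** Within a channel, the cluster with the lowest
center is the lesion (lesions are darker); `polarity="light"` flips this.
With more than two clusters, every cluster whose center lies below the
membership-weighted mean intensity counts as lesion and their memberships
are summed. The multi-cluster rule reflects how a preselected cluster count
larger than two fragments the scene: the principal lesion plus possible
darker satellite regions all contribute to the score.

**K-means score.** K-means has no memberships, so its score is the soft
ratio 1 − d_lesion/(d_lesion + d_nearest_other) per pixel: 1 at the lesion
centroid, 0.5 on the decision boundary, below 0.5 elsewhere. It is a
heuristic surrogate — adequate for ranking pixels (the ROC), less calibrated
around the default 0.5 threshold than the FCM memberships.

## Wavelet features

One-level (default) Mallat pyramid decomposition per channel, delegated to
PyWavelets. Conventions:

- **Boundary extension**: symmetric (half-sample) by default — standard for
  images, avoids edge artifacts. Configurable; the orthonormal
  energy-conservation (Parseval) property holds under the `periodization`
  mode, which is the convention the energy test uses, since symmetric
  extension is redundant (more coefficients than samples).
- **Scales**: J = 1 by default. One decomposition step already halves the
  spatial bandwidth of the noise while preserving the lesion's intensity
  step; deeper pyramids trade boundary localization for little gain at the
  128–600 px image sizes targeted.
- **Magnitude**: the detail magnitude is the *squared* sum
  D_h² + D_v² + D_d², the form adopted throughout; `magnitude_sqrt=True`
  gives the Euclidean magnitude. The two differ by a monotone transform, so
  only the geometry of cluster centers changes downstream.
- **Phase**: Θ = α where D_h > 0 and π − α where D_h < 0. At D_h = 0 the
  update is undefined; the implementation takes the arctan limit — π/2 for
  D_v > 0, 3π/2 for D_v < 0, and 0 when both vanish — and reduces Θ into
  [0, 2π).
- **Registration**: symmetric extension makes subbands longer than half the
  input, and the filter group delay shifts them spatially. The feature path
  crops each subband by the filter's energy-centroid delay before
  resampling, so features stay registered with the image; without this the
  boundary of the upsampled feature is displaced by several pixels for the
  longer banks, which measurably costs boundary accuracy.
- **Feature image**: approximation (default) or magnitude at scale J,
  nearest-neighbor resampled to the input shape, affinely rescaled to
  [0, 255]; a constant map is returned unchanged (degenerate-range rule).
  The approximation carries the intensity contrast that separates lesion
  from skin; the detail magnitude captures texture and is provided as an
  alternative feature rather than the default.

Filter banks for wavelet-atomic-function families (up₂, fup₂, π₆, e₂) are
supported only through user-supplied coefficient files, as no published
coefficient sets are available to embed.

## Clustering

FCM parameters: fuzziness k = 2 (the common default; k→1 approaches hard
clustering), convergence |ΔE| ≤ 1e-5, max 300 iterations. These are
documented defaults, not fitted values. Determinism conventions, chosen so
identical inputs give bit-identical results:

- K-means initialization is farthest-point seeding started from the point
  closest to the global mean; the `seed` argument only affects optional
  randomized restarts.
- FCM initialization is equidistant seeding across the data range — the
  same rule the preselection stage uses.
- argmin ties resolve to the lowest cluster index; an emptied K-means
  cluster re-seeds at the point farthest from its centroid.
- A point coinciding with one or more centers takes the limiting
  memberships: uniform over the coinciding centers, zero elsewhere.

The objective E is recorded every iteration and asserted non-increasing in
the tests — the standard alternating-minimization guarantee.

## Cluster-count preselection

Three linguistic variables with Gaussian sets
exp(−(x − center)²/(2·spread²)): six Distance sets on [0, 255] (centers
15, 53, 105, 150, 222, 255), five Size sets up to 1.44e6 pixels, five
Cluster sets (centers 2, 7, 16, 23, 33). The tabulated "variance" values
are interpreted as the spread σ, not σ²: on a 0–255 universe values like
16–45 are plausible widths, whereas as variances the sets would be
needle-thin and leave most of the universe uncovered.

The 30 rules (one per distance × size pair) are not canonically fixed, so
the default is the monotone grid: antecedent ranks (i, j) map to consequent
rank clamp(round((i + j − 1)/2), 1, 5) — small range and small image give
"very few", full range and large image "too many". The rule base loads from
a text file (`distance_label, size_label -> cluster_label` per line) so
alternative rule sets can be substituted. Defuzzification evaluates Q(c) on
integer c ∈ [2, 40] and takes the argmax, smallest c on ties: cluster
counts are integers, and centroid defuzzification would not return one.

Channel fusion computes pairwise channel dissimilarity as the sum of
squared per-pixel differences (no square root — monotone-equivalent to the
Euclidean distance for pair selection) and averages the two most similar
channels. Equidistant seeding is offset by V_min, c_j = V_min + jD/N, so
centers lie inside the image's actual intensity range rather than in
[D/N, D].

**Range sensitivity.** The preselector reads the literal range
D = V_max − V_min. On smooth clinical photographs D mostly reflects scene
contrast, but D is an extreme statistic: over ~16k pixels, iid Gaussian
noise alone spans roughly ±4σ, i.e. ~120 gray levels at σ = 15. On noisy
synthetic fixtures the inferred count therefore tracks noise amplitude as
much as lesion contrast — low-contrast images land in the "very few" band
only when nearly noise-free. This is a property of the range-based design,
deliberately kept: robust quantile ranges would change the method. In the
wavelet pipeline the preselector reads the *raw* channel, not the feature
image, because feature images are affinely rescaled to [0, 255] and would
present every image with D = 255.

## SRM baseline

The merge bound b(R) = g·sqrt(ln(2/δ)/(2·Q·|R|)) with g = 256 and
δ = 1/(6|I|²) is the canonical formulation; the predicate compares each
channel's average difference to sqrt(b²(R) + b²(R′)). An `as_printed`
variant comparing against b²(R) + b²(R′) without the square root exists
behind a flag; it is dimensionally odd (squared gray levels against gray
levels) and not the default. Pixel pairs are 4-connected, sorted by maximum
channel absolute difference with index tie-breaks, merged once through a
union-find — fully deterministic. For ROC comparison SRM's continuous score
is the min–max-inverted region mean intensity (darkest region → 1).

## Synthetic data

The generator emulates the relevant structure of dermoscopy photographs: an
irregular darker lesion (ellipse with radius modulated by random Fourier
harmonics 2–5), a radially graded interior (darker core, amplitude 0.6 ×
contrast, mean-centered so the configured mean contrast is exact), a small
zero-sum color tint (browner lesion, so channel ranges differ as they do in
practice), and additive iid Gaussian noise, clipped to [0, 255]. The mask
is the exact pre-noise region. All randomness flows from a single seed
through numpy's PCG64 generator.

What it does **not** emulate: hair and ruler occlusions, vignetting,
specular highlights, JPEG artifacts, spatially correlated skin texture, and
multi-modal lesion pigmentation. Passing tests on these fixtures shows the
pipeline recovers a known two-class geometry under controlled contrast and
noise; it does not certify clinical performance on atlas imagery.

The evaluation suite is the 3 × 3 grid contrast {30, 60, 100} × noise σ
{5, 15, 25} at 128 × 128 (sub-minute runtimes; 600 × 600 is a config
option). Construction guarantees that thresholding the noiseless gray image
at the contrast midpoint recovers the mask exactly, so AUC → 1 is
attainable in the noiseless limit by design.

A second fixture, `two_region_image`, is a noiseless two-level image whose
rectangular "lesion" sits on even pixel coordinates. It exists because
*exact* sensitivity = specificity = 1 is only attainable when no feature
cell straddles the class boundary: a 2×2 Haar approximation block crossing
a curved lesion border carries one value for pixels of both classes, making
perfect separation geometrically impossible on elliptical fixtures for the
wavelet variants (they reach optimal-threshold rates ≈ 0.98–1.0 there
instead). On the block-aligned fixture with the Haar bank, all six
clustering frameworks are exactly lossless, and the wavelet and plain
variants produce identical masks.

## Numerical and degenerate-input choices

- Constant image or channel: uniform 0.5 score, single cluster, warning.
- Rescaling a constant map to [0, 255] returns it unchanged.
- Empty lesion or skin class in a ratio: NaN, not an exception, so batch
  tables stay rectangular; a single-class ground truth in the ROC sweep is
  an error.
- ROC threshold rule: mask = (score ≥ t), thresholds descending, (0,0) and
  (1,1) anchors appended, trapezoidal AUC. This fixes tie handling so the
  trapezoidal area equals the Mann–Whitney statistic with half credit for
  ties (asserted to 1e-12 in the tests).
- Seeds are kept below 2³¹ so they survive any 32-bit RNG interface.

## Known limitations

- The kmeans soft score is not calibrated; its default-threshold masks can
  be conservative even when its ROC is excellent.
- The preselector's range statistic conflates contrast with noise (above).
- SRM merging is O(pairs × α) in pure Python/numpy; fine at 128–600 px,
  not tuned for megapixel images.
- Magnitude-mode features discard the approximation contrast and are weak
  stand-alone lesion features on low-texture imagery; they are provided for
  completeness and texture-oriented experimentation.
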