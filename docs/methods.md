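# Methods

## Problem and pipeline

Screening mammograms show the breast as a single bright region on a dark
background, frequently with scanner artifacts and identification labels
along the frame edge. The pipeline classifies a lesion (calcification or
mass) as benign or malignant from texture statistics computed inside a
region of interest, which is either a radiologist-drawn lesion mask
(`mask_mode="roi"`) or the automatically segmented whole breast
(`mask_mode="breast"`). Stages: segmentation → feature extraction →
conditioning → genetic-algorithm selection → logistic classification →
cross-validated reporting.

## Segmentation

Candidate tissue is every pixel with intensity **strictly greater than
50** on the 0–255 scale. A margin of `floor(0.05 · height)` rows and
`floor(0.05 · width)` columns is cleared on each side *before* component
selection, so an edge artifact can never bridge into the breast
component; the largest 8-connected component of what remains is the
breast mask. Equal-area ties break toward the component whose first
pixel comes earliest in row-major order — deterministic and seed-free.
16-bit images are linearly min–max rescaled to 0–255 first, because the
threshold is defined on that scale; the rescale rule is a package
choice (the intensity mapping for high-bit-depth inputs is otherwise
underdetermined) and is exposed through `GrayImage.to_8bit`. No
morphological opening/closing is applied by default; none is needed on
inputs whose background and tissue are separated by the threshold.

## Feature registry (94 features)

Texture families use IBSI-style definitions: first-order (19), GLCM
(24), GLRLM (16), GLSZM (16), NGTDM (5), GLDM (14). Choices that the
standard leaves open:

- **Discretization**: fixed bin width 25 on the 0–255 scale
  (≈ 11 gray levels), minimum taken over in-mask pixels only, which
  makes every feature translation-invariant and independent of
  out-of-mask content. Configurable via `FeatureConfig.bin_width`.
- **Directions**: GLCM and GLRLM use the four 2D directions 0°, 45°,
  90°, 135° at distance 1; feature values are averaged over directions.
  GLCM matrices are symmetric (each pair counted in both orders) and
  normalized per direction.
- **GLCM set**: the 24-feature registry keeps SumAverage and excludes
  the matrix-correlation feature that requires an eigendecomposition;
  every feature name that appears in the stable-gene tables of the
  motivating experiments (Contrast, Difference Entropy/Variance/Average,
  Id/Idn, IMC1/2, Inverse Variance, Joint Energy/Entropy, Maximum
  Probability, Sum Squares, Correlation, …) is present.
- **GLDM**: a neighbour is dependent if its level differs from the
  centre by at most `alpha` (default 0) within Chebyshev distance 1.
  The reported dependence of a pixel is its dependent-neighbour count
  (a lone pixel has dependence 0); feature formulas use dependence
  size = count + 1 so small/large-dependence emphases are defined for
  every pixel.
- **Degenerate limits**: 0·log 0 = 0 everywhere; denominators carry an
  ε = 2.2e−16 guard; NGTDM Coarseness is capped at 1e6 when its
  denominator vanishes. Every feature is finite on every nonempty ROI.
- **Shape family**: a compact 2D set (area, perimeter, axis lengths,
  row/column diameters) exists behind `include_shape=True` but is off
  the default texture-only path.

First-order statistics use population (1/N) moments; Entropy and
Uniformity are computed on the fixed-bin-width histogram; TotalEnergy
scales Energy by the physical pixel area (default 1.0).

## Conditioning and genetic-algorithm selection

Zero-variance columns are removed, then every column is standardized to
mean 0 and unit sample (n−1) standard deviation. Inside any
cross-validation, whitening statistics are recomputed on the training
partition only.

The GA evolves chromosomes of `chromosome_size = 5` distinct feature
indices (population 50, at most 300 generations by default) with
tournament selection of size 2, elitism of 1, single-point crossover
with duplicate repair, and per-gene mutation at rate 0.05 toward a
fitness goal of 0.90. Fitness is stratified 3-fold inner-CV accuracy of
a 3-nearest-neighbour classifier on the whitened subset; the 3-NN
scorer is a vectorized in-package routine verified against
scikit-learn, and logistic or random-forest fitness can be selected in
`GAConfig.classifier`. `collect_solutions` runs `n_solutions = 100`
independent evolutions (child seeds spawned from the master seed);
features are then ranked by their appearance frequency across final
solutions (gene-rank stability), ties broken by mean within-chromosome
position and then name. A greedy forward pass over the top-ranked genes
(default 7) keeps a gene only when it strictly improves inner-CV
accuracy.

## Classification and validation

Logistic regression is fitted by IRLS (Newton–Raphson), converged when
the largest coefficient update falls below 1e−8, capped at 100
iterations; perfect separation yields `converged=False` with the
capped coefficients — a warning, not a failure. The printed closed
forms (intercept-only fit equals log n₁/n₀) and a dense grid-search
oracle pin the implementation in the tests. Classification uses
probability ≥ 0.5, boundary inclusive. AUC is the Mann–Whitney
statistic with half-credit for ties. AIC = 2k − 2 log L is reported for
the full-data refit (a single value per model), not averaged over
folds.

`kfold_cv` stratifies by class, shuffles with the given seed, and
pools metrics as the arithmetic mean over folds. Because the fold count
must not exceed the size of the smaller class under stratification,
leave-one-out on a balanced cohort is rejected rather than silently
de-stratified. Two evaluation modes exist because reported headline
metrics can mean either: `cv_selection="refit"` (default) reruns the
whole GA selection inside every training fold — unbiased, and what the
pooled metrics mean here — while `"fixed"` evaluates one externally
chosen gene list; the full-data refit metrics are reported alongside in
either mode.

## Synthetic cohorts

`make_mammogram` draws a dark background (uniform 5–25), a bright
half-elliptical breast (base ≈ 140 with smooth large-scale texture,
clipped to ≥ 110) anchored near the left frame edge but clear of the 5%
margin, a 220-intensity label box inside the margin, and a lesion in a
circular radiologist-style ROI. Class information is **texture-only**:
malignant masses get shorter-correlation-length internal noise
(Gaussian-filtered noise with σ shrinking from 3.0 by 1.8·texture_effect),
malignant calcifications a denser bright-speckle cluster (density
0.006 + 0.020·texture_effect). At `texture_effect = 0` the class
distributions are identical. Defaults are 40 samples, balance 0.5,
256×256 pixels — a desk-scale stand-in for a curated screening cohort,
not a photorealistic simulator: it has no pectoral muscle, no density
grades, no scanner noise model, and its background/tissue intensities
are separated by construction, so passing segmentation tests show
correctness of the algorithm, not robustness to low-contrast clinical
images. `make_feature_table` plants `n_informative` class-shifted
Gaussian columns (shift = effect_size) among standard-normal noise and
records the planted indices.

## Problem sizes used in the test suite

The shipped tests run the GA at a reduced compute setting chosen as the
package's desk scale — population 16, 20 generations, 8 solutions for
the end-to-end cohorts, and `n_solutions = 30` for the planted-feature
recovery check — with the cohort conditions themselves (40 images at
256×256, 3-fold CV, effect sizes) unreduced. Recovery and null behaviour
are assessed as means over 20 master seeds.

## Known limitations

- 2D only; no resampling, no filtered-image (wavelet/LoG) features.
- The segmenter assumes one dominant bright region; two-view frames or
  breasts touching more than one edge are out of scope.
- The GA explores a small fraction of subset space; with highly
  correlated radiomic features, different seeds can return different
  but equally predictive chromosomes — the stability ranking, not any
  single chromosome, is the reliable output.
- Under perfect separation the logistic coefficients are reported at
  the iteration cap and their standard errors are not meaningful.
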