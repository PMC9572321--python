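# Methods

This note records the models, conventions and design choices behind
`ripegrade`, and what the synthetic experiments do and do not show.

## Segmentation

The fruit is separated from the near-white background in five steps:
threshold the gray level, invert, morphologically clean, fill/filter
components, and mask the background.

- **Threshold.** Otsu on the BT.601 gray level by default; a fixed
  threshold is available (`PreprocessConfig`). Otsu is parameter-free
  and well suited to the strongly bimodal histogram of a dark fruit on a
  white field, but it fails (by design, with a `DegenerateHistogramError`)
  on constant images.
- **Polarity.** After thresholding, polarity is normalized so that the
  border pixels — assumed background — map to `True`. On white-background
  scenes this is exactly "bright background → true"; it also makes the
  pipeline idempotent on an already background-removed (black-background)
  image, which is a tested invariant.
- **Morphology.** Opening then closing with a disk of radius 2 px. The
  source procedure lists "erosion and dilation" without an order;
  opening-then-closing is this package's choice: opening removes
  isolated specks and thin protrusions first, closing then repairs small
  boundary gaps. Radius 2 is the smallest element that removes
  single-pixel noise without materially eroding the fruit boundary.
- **Component filtering.** Interior holes are filled, components smaller
  than 0.1% of the image area are dropped, and only the largest
  remaining component is kept — there is exactly one fruit per image, so
  shadows and residual specks are removed structurally rather than by
  illumination modeling.

## Color channels

All channels are computed per pixel from RGB in [0, 1]:

- gray = 0.2989 R + 0.5870 G + 0.1140 B (full-precision NTSC/BT.601
  weights, normalized to sum exactly 1 so the chromatic deviations below
  vanish identically on achromatic pixels);
- Ohta I1 = (R+G+B)/3, I2 = (R−B)/2, I3 = (2G−R−B)/4 — the standard
  decorrelated space of agricultural vision work;
- chromaticities nr = R/(R+G+B) etc., defined 0 where the sum is 0;
- chromatic deviations cr = R − gray, cg = G − gray, cb = B − gray.
  The CrCgCb space is not printed in the source work; the
  deviation-from-gray definition is chosen because it produces signed
  values consistent with the negative published Cb class means, and is
  flagged as an interpretation;
- HSV by the hexcone model (H scaled to [0, 1], H ≔ 0 where S = 0);
- CIELAB via sRGB primaries and the D65 white (consumer-camera images).

Channels operate on unit-scaled RGB, consistent with the magnitude of
published per-class B-channel means (~0.23–0.32).

The published per-class means of the chromaticity channels (~1e-4) are
inconsistent with any per-pixel normalization, whose fruit averages are
necessarily ≈ 1/3; the standard definition is kept and those rows are
not used for calibration.

## Features

Per channel, nine first-order statistics over fruit pixels and six
texture features from a gray-level co-occurrence matrix (GLCM), 285 in
total, named `<statistic>_<channel>`.

Conventions (all features are finite by construction):

- population moments; skewness m3/m2^1.5 and kurtosis m4/m2² — the
  **non-excess** kurtosis convention (Gaussian → 3), consistent with
  published per-class kurtosis values clustering near 3;
- cv = σ/mean, set to 0 for a zero mean; mode = midpoint of the densest
  of 256 equal-width bins (a raw-value mode is ill-defined on reals);
- zero-variance samples: σ, cv, skewness and kurtosis are all reported
  as 0 (the sample is constant up to rounding);
- GLCM: 8 quantization levels over the masked min–max range, the four
  distance-1 offsets, symmetric counting, per-offset normalization, then
  averaging — common texture-analysis defaults, all configurable
  (`GlcmConfig`). Only pixel pairs **both** inside the fruit mask are
  counted; background values can be altered arbitrarily without changing
  any feature (tested invariant). A region with fewer than two valid
  pairs raises `DegenerateRegionError`.
- texture measures: contrast Σp(i,j)(i−j)², homogeneity Σp/(1+|i−j|),
  energy Σp², entropy −Σp log₂p (0·log 0 = 0), covariance
  Σp(i−μᵢ)(j−μⱼ), correlation = covariance/(σᵢσⱼ) with the convention
  correlation ≔ 1 when σᵢσⱼ = 0. "Covariance" is read as the GLCM
  covariance (the numerator of GLCM correlation), since it is listed
  among the texture features; channel-pair covariance is the plausible
  alternative reading.
- First-order statistics use fruit pixels only: background removal
  precedes feature extraction in the pipeline, so statistics over the
  full frame would mostly measure the background.

## Feature selection

"Quadratic sequential feature selection" is implemented as **forward**
sequential selection scored by stratified k-fold cross-validated QDA
misclassification (default 5 folds — 40 images/class supports 5 clean
folds). Each candidate subset is z-scored on the training folds before
the QDA fit. The stop rule is "no strict improvement", with an optional
`max_features` cap; the criterion sequence over accepted steps is
strictly decreasing by construction. Fold assignment is derived from a
canonical row order (class, then image id), so selection is invariant to
row shuffling; candidate ties break by registry column order. Backward
and floating variants are out of scope.

The 16-feature subset reported optimal on the original fruit images is
shipped as a named registry constant (`OPTIMUM_FEATURES`); selection on
other data has no reason to reproduce it, so pipelines can either run
selection or use the fixed list.

## Classifiers

**LDA/QDA.** Gaussian class-conditional fits: pooled within-class
covariance (LDA) or per-class covariances (QDA), empirical priors by
default. Features are z-scored on the training data (raw features span
~1e-4 to >20). A ridge of 1e-6 (on the correlation scale) is added
whenever a covariance's smallest eigenvalue falls below 1e-8 — with 16+
features and ~32 training images per class, collinearity is a real
possibility; with regularization disabled, a singular fit raises instead
of silently pseudo-inverting. Prediction is the argmax of the Gaussian
log-posterior; exact ties go to the earliest class in display order.
Protocol: stratified 80:20 train/test split (stratification preserves
the 40-per-class balance at this sample size; the source protocol says
only "randomly divided").

**Shallow network.** n inputs → h tanh hidden units → 4 linear outputs,
trained by mean squared error against one-hot membership targets.
Inputs are min-max scaled to [−1, 1] per feature. The optimizer contract
is "any method that monotonically reduces training MSE with early
stopping on validation MSE"; the implementation is full-batch gradient
descent with a backtracking line search (step ×1.2 on acceptance, ×0.5
on rejection), which makes every epoch strictly decrease the training
MSE and keeps training fully deterministic under the seed. Early
stopping uses a patience of 6 epochs on validation MSE, and the weights
of the best-validation epoch are restored (the reported validation MSE
equals the history minimum — a tested invariant). Defaults: 400 epochs
maximum, initial step 0.1, uniform ±1/√fan-in initialization.
Protocol: stratified 60:20:20 train/validation/test split. The structure
scan trains one network per hidden width (2..20, each with its own
seed-derived initialization) and reports validation MSE, test-set
Pearson r of outputs vs one-hot targets, and whole-dataset CCR; the
optimum is the highest CCR, then highest r, then lowest validation MSE.
Whole-dataset CCR includes training samples — that definition is
reproduced deliberately because it is how the scan is reported in the
source protocol; the per-width table also carries test-only CCR.

## Evaluation

CCR = 100·trace/total of the confusion matrix (rows = actual, columns =
predicted, display order *overripe, ripe, secondary unripe, initial
unripe*). For hard classifiers the reported "MSE" is the
misclassification fraction, identically 1 − CCR/100 (the published
LDA/QDA numbers satisfy this identity exactly: 10/160 = 0.0625,
4/160 = 0.0250); it is implemented separately from the network's output
MSE (mean squared one-hot error), and the two are never mixed. The
evaluation scope defaults to the whole dataset, mirroring the published
confusion matrices whose row sums equal the full class sizes; test-only
reports are always emitted alongside.

## Synthetic data

The generator emulates the study design: four ripeness classes × 40
images, one elliptical fruit per frame on a near-white background.

- **Color profiles.** The only quantitative per-class color statistics
  available are published channel means; the default profiles anchor
  each class's mean color to its published H and S means, with V solved
  so the mean of B also matches its published row (overripe H=0.1439,
  S=0.1836; ripe H=0.3932, S=0.1659; secondary unripe H=0.2472,
  S=0.5008; initial unripe H=0.1491, S=0.2840). The qualitative stage
  descriptions (whitish → pink-red → bluish → green) are internally
  inconsistent with those means; the quantitative anchors win.
- **Within-fruit texture.** Fruit color is mean + correlated Gaussian
  noise: white noise smoothed at a 3 px correlation length and scaled by
  the profile covariance (default isotropic, σ = 0.01 per channel).
  Correlated rather than i.i.d. noise keeps the GLCM features
  non-degenerate. The smoothed field is normalized by the exact L2 norm
  of the Gaussian kernel — normalizing by the empirical std would couple
  the field's regional mean to the shared std estimate and bias masked
  channel means. σ = 0.01 keeps the nonlinear channels (H, S) within
  sampling error of their anchors; larger noise visibly biases hue for
  the two near-achromatic classes, whose channel differences are only a
  few times larger.
- **Scene.** 120×160 px frames (an A4-like aspect), background RGB
  ≈ (0.97, 0.96, 0.95), semi-axes 26×38 px jittered ±10% with random
  orientation and ±5 px center jitter per image, additive sensor noise
  σ = 0.004, and a soft multiplicative shadow lobe (strength 0.15, the
  fruit ellipse translated and blurred, restricted to outside the
  fruit). The fruit outline is regularized by a radius-2 open-close so
  the rasterized ellipse carries no single-pixel protrusions — real
  fruit outlines are smooth at pixel scale, and this makes the
  segmentation invariants exact rather than approximate. All generation
  is deterministic under a single seed (per-image generators derived via
  seed sequences).
- **What passing does not show.** The synthetic classes are separated by
  ~5σ in mean-feature space, so 100% CCR on them demonstrates pipeline
  correctness (plumbing, conventions, determinism, separability
  transfer), not real-world accuracy. The generator has no specular
  highlights, no inter-fruit shape/size taxonomy, no illumination
  gradients, no camera noise model beyond additive Gaussian, and no
  within-class color multimodality; published real-image accuracies
  (93.75 / 97.5 / 100%) cannot be reproduced or refuted with it because
  the original images are not deposited.

## Problem sizes and numerical choices

The shipped experiments use the study-sized design (160 images at
120×160 px) for the end-to-end checks and reduced scenes (60×80 px, 6
images/class) for unit-level tests. Degenerate-input behavior is
specified and tested throughout: constant images, empty masks,
sub-2-pair GLCM regions, singular covariances, zero-variance
correlation inputs, and ties in classifier argmax all have defined
outcomes (error or documented convention) rather than NaNs.

## Known limitations

- Single fruit per frame, controlled white background; no field or
  orchard segmentation, no color calibration or white balance.
- The CrCgCb definition and the "covariance" texture feature are
  documented interpretations of under-specified names.
- The sequential-selection criterion (folds, stop rule) is this
  package's concrete instantiation of a method named only generically in
  the source protocol; different instantiations select different
  subsets.
- The shallow network is intentionally minimal (no momentum, no
  mini-batching); it is adequate for ≤ 300 samples × ≤ 20 hidden units,
  not for large-scale training.
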