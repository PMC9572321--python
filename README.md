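# ripegrade

Machine-vision grading of fruit ripeness from color images of single
fruits on a white background, for researchers in post-harvest quality
assessment and agricultural machine vision.

A fruit's exterior color changes systematically as it matures, so a
low-cost visible-light camera can stand in for destructive maturity
assays. `ripegrade` implements a classical feature-engineering pipeline
for four-stage ripeness grading (*overripe, ripe, secondary unripe,
initial unripe*):

1. **Segmentation** — binarize the BT.601 gray level (Otsu by default),
   invert, morphologically open/close, fill holes, keep the largest
   component, and remove the background.
2. **Channel decomposition** — 19 scalar channels from six color spaces:
   R, G, B; Ohta I1, I2, I3; CIELAB L\*, a\*, b\*; chromaticities nr, ng,
   nb; chromatic deviations cr, cg, cb; H, S, V; and gray.
3. **Feature extraction** — per channel, 9 first-order statistics (min,
   mean, max, σ, cv, median, mode, skewness, kurtosis) over fruit pixels
   and 6 texture measures (homogeneity, covariance, contrast,
   correlation, entropy, energy) from a mask-aware gray-level
   co-occurrence matrix (GLCM): 15 × 19 = **285 features per image**.
4. **Feature selection** — quadratic sequential forward selection: add
   the feature minimizing the stratified cross-validated QDA error until
   no candidate improves it. A fixed 16-feature reference subset (e.g.
   `mean_B`, `skewness_Lstar`, `mean_H`, `mean_S`, …) is also built in.
5. **Classification** — linear/quadratic discriminant analysis
   (80:20 split) and a single-hidden-layer network, *n*‑*h*‑4 with tanh
   hidden units (h ∈ 2..20) and linear outputs trained by MSE against
   one-hot targets (60:20:20 split with early stopping); a structure scan
   picks the optimal hidden width.
6. **Evaluation** — confusion matrices, correct classification rate
   CCR = 100·trace/total, misclassification "MSE" for hard classifiers,
   output MSE and Pearson r against one-hot membership for the network.

Because suitable public image sets of graded fruit are scarce, the
package ships a first-class synthetic generator: elliptical fruit blobs
with class-specific color distributions (spatially correlated noise, so
texture features are non-degenerate) on a near-white A4-like background
with a soft shadow — the same study design the pipeline targets (4
classes × 40 images).

## Worked example

```bash
ripegrade pipeline --out run/ --seed 1
```

generates 160 synthetic images (40 per class), segments them, extracts
the 285-feature table, trains LDA and QDA on the 16-feature reference
subset, scans network structures 16-2-4 … 16-20-4, and prints:

```
lda: CCR 100.00%  MSE 0.0000
qda: CCR 100.00%  MSE 0.0000
ann: CCR 100.00%  MSE 0.0000
```

CCR is the percentage of all 160 images assigned their true stage; MSE
is the complementary misclassification fraction. The default synthetic
classes are well separated in color, so all three classifiers reach
100% — the interesting structure is in `run/scan.csv`, the per-width
scan table (validation MSE, test-set correlation r, whole-dataset CCR):

```
structure,n_hidden,validation_mse,test_r,ccr_all,ccr_test
16-2-4,2,0.06269,0.81593,75.0,75.0
16-3-4,3,0.00039,0.99881,100.0,100.0
16-4-4,4,0.00061,0.99820,100.0,100.0
...
```

Two hidden units cannot carve four one-hot outputs from 16 inputs
(75% CCR, r ≈ 0.82); three and more can. `run/` also contains
`features.csv`, serialized models (JSON), evaluation reports, and a
manifest with SHA-256 hashes — rerunning with the same seed reproduces
the CSVs byte-for-byte.

The same stages are available as library calls (`generate_dataset`,
`preprocess_pipeline`, `extract_table`, `sfs_quadratic`,
`DiscriminantClassifier`, `ShallowNetClassifier`, `scan_structures`) —
the classifiers and the selector follow the scikit-learn estimator API
and compose with sklearn pipelines and model selection.

Published confusion matrices can be scored directly:

```python
import pandas as pd, ripegrade as rg
cm = pd.DataFrame([[39,0,0,1],[7,33,0,0],[0,0,39,1],[0,0,1,39]],
                  index=rg.CLASS_ORDER, columns=rg.CLASS_ORDER)
rg.ccr(cm), rg.classifier_mse(cm)   # (93.75, 0.0625)
```

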