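# octfluid

Region-based characterization of intraretinal cystoid fluid in OCT B-scans.

Intraretinal fluid accumulations (cysts) are a key biomarker of exudative
macular disease and macular edema. Instead of segmenting cyst contours —
fragile when borders are blurred or cysts merge — this package classifies
*regions*: square windows inside the retina are labeled as cystoid or
non-cystoid from their intensity and texture statistics. It is aimed at
researchers studying which texture descriptor families discriminate
hyporeflective fluid from retinal tissue, and at anyone needing a
reproducible benchmark harness for that question.

## What it does

1. **Layer delimitation** (`octfluid.layers`). The region of interest lies
   between the inner limiting membrane (ILM) and the retinal pigment
   epithelium (RPE). Pixels form a graph whose edge weights are
   `2 − (g_a + g_b) + w_min`, with `g` the normalized vertical dark-to-light
   gradient; Dijkstra shortest paths from one side of the image to the other
   trace the two strongest interfaces. Virtual low-cost columns on both
   sides let paths start and end at any row.
2. **Window sampling** (`octfluid.sampling`). Overlapping W×W windows
   (default W = 61) with centers inside the ILM–RPE band; a window is
   cystoid when ≥ τ (default 5%) of its in-ROI pixels are fluid.
3. **Feature battery** (`octfluid.features`). A 510-value descriptor per
   window: global intensity statistics (GIBS, 15), per-axis skewness/kurtosis
   (AIS, 12), singular-value spectrum of the ROI rectangle (28), local
   energy shape histogram on phase congruency (LESH, 128), gray-level
   co-occurrence statistics at distance 2 in 4 directions (GLCM, 16),
   histogram of oriented gradients (HOG, 3×3 cells × 9 bins = 81), an
   8-frequency × 8-orientation Gabor bank (mean + sd = 128), local binary
   patterns over neighbors {4, 8, 12, 16} × radii 1–8 (64), Laws texture
   energy (28), box-counting fractal features (3), and gray-level run-length
   statistics over 4 orientations (GLRL, 7).
4. **Feature selection** (`octfluid.selection`). Three sklearn-compatible
   selectors: iterative trace-ratio maximization (maximizes
   tr(between-class scatter)/tr(within-class scatter) over k-feature
   subsets), Relief-F, and extra-randomized-trees importances.
5. **Evaluation protocol** (`octfluid.evaluation`). Repeated stratified
   k-fold CV (10×10 by default); selectors are fitted per training fold
   only; seven classifiers (LDA, ridge, linear and RBF SVM, distance-weighted
   kNN with k = 15, random forest, gradient boosting) are trained on nested
   ranking prefixes of size 1..100, yielding accuracy-vs-subset-size curves,
   best-result tables and per-category relevance analytics.

Because no clinical dataset ships with the package, `octfluid.phantom`
generates OCT-like B-scans with known ground truth: bright layered bands, a
foveal dip, multiplicative gamma speckle, dark elliptical cysts strictly
between the ILM and RPE, vertical shadow columns and drusen-like RPE bumps.

## Worked example

```python
import numpy as np
from octfluid import (PhantomSpec, generate_bscan, segment_ilm_rpe, roi_mask,
                      extract_windows, extract_all)
from octfluid.layers import boundary_mae

scan, truth = generate_bscan(PhantomSpec(seed=3))
bounds = segment_ilm_rpe(scan)
print("ILM MAE %.2f px, RPE MAE %.2f px"
      % (boundary_mae(bounds.ilm_row, truth.ilm_true),
         boundary_mae(bounds.rpe_row, truth.rpe_true)))

roi = roi_mask(bounds, scan.pixels.shape)
windows = extract_windows(scan, roi, w=61, source_id=scan.id)
vec = extract_all(windows[0])
print("windows:", len(windows), "| descriptor length:", vec.shape[0])
```

prints

```
ILM MAE 0.47 px, RPE MAE 1.16 px
windows: 31 | descriptor length: 510
```

— the recovered boundaries track the true layers to about a pixel despite
speckle, and each window yields the full 510-value descriptor. The same
pipeline is available from the shell:

```bash
octfluid phantom  --out scans/ --n 10 --seed 0
octfluid extract  --images scans/ --out feats/
octfluid evaluate --features feats/features.csv --out reports/ \
                  --folds 10 --repeats 10
```

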