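# Methods

This note records the models, conventions and numerical choices behind
`octfluid`, in the order the pipeline runs.

## Synthetic B-scan generator

The phantom emulates the image properties the analysis assumes, not OCT
device physics. A noise-free reflectance template is built first: dark
background (mean 25), a retina of `n_layers = 4` bright bands (levels around
`tissue_mean = 170`) between per-column ILM and RPE rows, a hyporeflective
gap just above a bright RPE band (≈ 1.25 × tissue mean), and a foveal dip
modeled as a negative Gaussian added to all layer rows (amplitude 12 px,
width ≈ image width / 5). Cysts are filled rotated ellipses of
`fluid_mean = 50` with Gaussian-feathered borders (a 30% "blurred-border"
fraction receives heavier feathering), clipped to lie strictly between the
layers. Drusen are local upward bumps of the RPE with hyperreflective fill;
shadows multiply all rows below a per-column origin by
`shadow_attenuation = 0.5`. Speckle is multiplicative gamma noise with shape
`k = 6` and scale `1/k` (unit mean) — the standard surrogate for fully
developed speckle; `k = inf` disables it. Everything is a pure function of
the spec (which includes the seed); images are quantized to 8 bits at the
end.

Defaults are desk-scale study conditions: 360 × 220 px images (jittered
±20/±10 px per image), a ≈ 100 px-thick retina so 61 × 61 windows fit, and
cyst load (5 cysts of 10–30 px semi-axes in every second image) chosen so
that grid-sampled windows fall in the 30–70% cystoid band before balancing.
What the phantom does **not** reproduce: real speckle correlation lengths,
device-dependent contrast, vitreous floaters, pathology beyond
cyst/shadow/druse, or annotation noise. Passing benchmarks on phantoms
therefore demonstrate that the pipeline's machinery is correct and that its
descriptors separate dark homogeneous ellipses from layered texture; they do
not certify clinical accuracy.

## Layer delimitation

The vertical gradient is a central difference along columns, computed
**before** Gaussian smoothing (σ = 1, truncated at 2σ) so that integer-valued
global intensity shifts cancel exactly and boundaries are bit-stable under
brightness changes; the dark-to-light polarity keeps positive downward
derivatives, and the map is min-max normalized per image (constant images
give all zeros). Edge weights are `2 − (g_a + g_b) + w_min` with
`w_min = 1e−5`.

The pixel graph allows the three column-advancing moves
{(+1,−1), (+1,0), (+1,+1)}; within-column vertical moves exist only in the
two virtual all-ones columns prepended/appended so a path may enter and
leave at any row. Restricting vertical moves to the virtual columns keeps
every source-to-sink path monotone in the column index, which makes the
minimum cost checkable against exhaustive enumeration over monotone paths —
the correctness oracle used in the tests. Paths are found with Dijkstra on
a sparse matrix; ties resolve deterministically.

Both the ILM and the top of the RPE band are dark-to-light interfaces. The
first shortest path follows the strongest one; a ±10-row band around it is
zeroed and the search repeated; the upper path becomes the ILM. The 10-row
margin is configurable; it only needs to exceed the gradient support width
and stay below the retina thickness. If the two paths touch or cross, a
`SegmentationError` carrying both raw paths is raised.

## Sampling and labeling

Windows sit on a raster grid (stride default round(W/2)); a window is kept
when its center is between the layers and the full W×W block fits in the
image — no padding is fabricated. Labels compare the cyst fraction of
in-ROI pixels against τ = 0.05: small enough to capture "presence" rather
than dominance, and checked monotone in τ by a property test. Balancing
down-samples the majority class with a seeded generator. The
maximum-area all-true rectangle of a window's ROI mask (used by the spectral
category) is found with the histogram-stack method; ties go to the smallest
(top, left).

## The 510-value descriptor

Category layout (1-based inclusive): GIBS 1–15, AIS 16–27, EIGEN 28–55,
LESH 56–183, GLCM 184–199, HOG 200–280, GABOR 281–408, LBP 409–472,
LAWS 473–500, FD 501–503, GLRL 504–510. Conventions that needed a decision:

* **GIBS** — variance/sd use the population (n) convention; entropy is
  Shannon entropy in bits over the 256-bin gray histogram; the six
  normal-fit slots are the ML mean, the n−1 sd, and their 95% confidence
  bounds (Student-t for the mean, chi-square for the sd), mirroring the
  usual normal-fit output.
* **AIS** — population skewness and Pearson (non-excess) kurtosis per row
  ("horizontal") and per column; zero-variance slices contribute 0 to both.
  Slot order per aggregate {min, mean, max}: (skew-h, skew-v, kurt-h,
  kurt-v).
* **EIGEN** — spectral magnitudes are singular values of the
  column-mean-centered ROI rectangle (well defined for non-square
  rectangles, and rank-1 inputs keep exactly one nonzero magnitude). For a
  non-square rectangle, a square window of side min(h, w) slides with
  stride side/2 and the sorted spectra are averaged element-wise.
  Magnitudes below 1e−10 of the largest are snapped to zero so the
  x/0 → 0 ratio convention applies to numerically-null values. The 18
  ratios are max_i/min_j (i, j ∈ 1..4), max1/max4 and min1/min4.
* **LESH** — Kovesi-style phase congruency with a 5-scale log-Gabor bank
  (minimum wavelength 3 px, scale multiplier 2.1, σ_onf 0.55), 8
  orientations with angular spread 1.2·π/8 (axial, 180°-periodic), noise
  threshold k = 2 Rayleigh standard deviations estimated from the
  smallest-scale response, ε = 1e−4. Each pixel adds its summed phase
  congruency to the orientation bin of its dominant-amplitude orientation,
  within a 4×4 spatial partition; the 128-vector is globally L2-normalized,
  making the descriptor contrast-invariant to < 1e−6 under intensity
  scaling.
* **GLCM** — uniform quantization of [0,255] to 8 levels; symmetric,
  normalized matrices at offsets (0,2), (−2,2), (−2,0), (−2,−2); energy is
  the angular second moment, homogeneity uses 1/(1+|i−j|), and a
  zero-variance marginal maps correlation to 0.
* **HOG** — central-difference gradients, unsigned orientation in 9 bins of
  20° with linear interpolation between bin centers (so a 0° gradient
  splits between the two bins flanking 0°), 3×3 cells, per-cell L2
  normalization with ε = 1e−6 (zero histograms stay zero); no block
  renormalization.
* **GABOR** — Gaussian-envelope complex sinusoid with frequency-tied σ =
  0.56/f, γ = η = √2, f_k = 0.25/√2^k (k = 0..7), θ_j = jπ/8; filtering is
  FFT-based with reflective padding (kernels truncated at 3σ, filter FFTs
  cached per block shape); features are the mean then sd of the response
  magnitude, frequency-major. The split is 64 means + 64 sds, the only
  reading consistent with an 8×8 bank producing 128 values.
* **LBP** — rotation-variant codes for neighbors {4, 8, 12, 16} × radii
  1–8, neighbor p at angle 2πp/P from east, computed on the interior where
  the full radius fits. The bilinear interpolation is applied to
  neighbor-minus-center differences, so a global additive shift cancels
  exactly in floating point and the 64 outputs are bit-identical under
  brightness offsets (a property skimage's formulation cannot guarantee at
  ties, which is why this category is implemented in-package).
* **LAWS** — 1-D kernels L3/E3/S3 and L5/E5/S5/R5; all outer products per
  size family, transposed pairs averaged after taking absolute responses,
  pure smoothing maps (LL) dropped: 5 + 9 = 14 energy maps, statistics over
  the 'valid' convolution region, means then sds with the 3×3 family first.
* **FD** — differential box counting on 16×16 local windows (stride 8;
  window 8 for small blocks) with box height s·256/M; scales {2, 4, 8} are
  chosen to divide the window so a flat patch yields dimension exactly 2.
  Lacunarity is var/mean² of the finest-scale box counts over all windows —
  a span-based quantity, hence shift-invariant like the dimension map.
* **GLRL** — quantization to 51 levels (⌊g·51/256⌋); run matrices of the
  four orientations (diagonal scan-lines for 45°/135°) are summed before
  computing SRE, LRE, GLN, RP, RLN, LGRE, HGRE; gray-level weights use
  1-based level indices and RP divides by the 4·H·W scanned pixels.

All categories operate on the full block except EIGEN, which uses the
inscribed ROI rectangle. `extract_all` is a pure function of (block,
roi_sub); one 61 × 61 window takes ≈ 0.2 s on one CPU.

## Feature selection

Trace ratio uses Fisher-style affinity graphs — cross-class pair weight
1/n, same-class pair weight 1/n_c — whose per-feature Laplacian quadratic
forms give between/within scatters b_i and w_i; the iteration
λ ← Σ_sel b / Σ_sel w with re-selection of the k largest b_i − λw_i
converges monotonically (cap 100 iterations, warning on non-convergence);
ties break to the lower index. Relief-F uses range-normalized Manhattan
per-feature distances, 10 nearest hits/misses, class-prior weighting, and
all samples as probes by default, which makes it deterministic and
order-independent. The forest selector wraps extra-randomized trees (100
trees, seeded). Distance-based selectors z-scale internally; the forest
consumes raw features.

## Evaluation protocol

Repeated stratified k-fold CV (stratification keeps both classes in every
fold, which the per-fold selector fitting requires). Selectors see only the
training rows; classifiers consume nested prefixes (sizes 1..max_features)
of each ranking. LDA, ridge (α = 1), both SVMs (C = 1, RBF γ = 1/(d·var)),
and kNN (k = 15, distance-weighted, clipped below 15 when the training fold
is smaller) receive features z-scaled with training statistics; the tree
ensembles (100 trees each) use raw features. Curves average all
repeat × fold accuracies per subset size; the best-result table adds
milestone sizes {1, 5, 10, 20, 30, 50, 70, 100} and the mean/sd of
successive-size accuracy differences over the last 50 sizes (the
stabilization statistic). Category analytics are computed at selector level
(rankings are classifier-independent): presence in the top-100, presence
proportional to min(100, category size), and the best-rank score
100·(100 − r)/99 with −1 for absent categories — the affine map that sends
rank 1 to 100 and rank 100 to 0. Pairwise feature correlations are absolute
Pearson values with constant features set to 0; category-pair means exclude
the self diagonal.

## Problem sizes

The shipped benchmark harness runs at desk scale: the end-to-end check uses
40 phantoms, 500 balanced windows, Relief-F + RBF-SVM with the top 50
features under 5×2 CV (it reaches ≈ 97% mean accuracy, with a label-permuted
control at chance), and the protocol-structure check runs the full
selector × classifier grid at 2 repeats × 3 folds × 5 subset sizes. The
full 10×10 × top-100 protocol is available through `run_cv`/the CLI and
scales linearly in repeats × folds × sizes.

## Known limitations

Segmentation assumes the RPE top is the second-strongest dark-to-light
interface; severe drusen or shadow coverage can violate this. The LESH
noise threshold is estimated per orientation from the smallest scale, a
simplification of Kovesi's full estimator. Eigen ratios are unstable for
near-singular spectra even after zero-snapping. The phantom's texture
statistics are qualitative: descriptor *rankings* measured on phantoms
should not be read as clinical conclusions.
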