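# Methods

This note documents the models, conventions and design choices behind
`ntcc`, the parameters that matter, and what the synthetic-data-based
validation does and does not establish.

## Segmentation

Single-cell crops are segmented by a deliberately simple morphological
recipe: invert the intensities (stained nuclei are the darkest
structures in the crop, so inversion makes them the brightest), apply
three-class Otsu thresholding to separate background / cytoplasm /
nucleus in one step, then clean the nucleus mask with a binary closing
(disk structuring element, radius 5 px by default), fill holes, and
keep the largest connected component of each region (ties broken by
row-major scan order of the labelling). The cytoplasm mask is the cell
region minus the nucleus, so the two masks are disjoint by
construction.

Choices worth noting:

* The three-class threshold is our choice; a plausible alternative —
  single Otsu for the cell followed by a second Otsu inside it — is
  available as `threshold_method="otsu2"`. Classical descriptions of
  this pipeline specify only the nucleus extraction; how the cytoplasm
  boundary is found is genuinely open, and the three-class variant was
  chosen because downstream features need both regions from one
  consistent step.
* The structuring element ("size five") is interpreted as a disk of
  radius 5 px; shape and size are configurable
  (`se_shape`, `se_radius`).
* Columnar-type cells can show almost no cytoplasm. When the visible
  cytoplasm falls below `min_cytoplasm_area` (default 25 px), the
  cytoplasm-dependent quantities (the F1 denominator, the F3 centroid)
  fall back to the whole cell region, which keeps NC bounded in (0, 1]
  and avoids division by zero.
* A contrast-free image (constant, or fewer than three distinct
  levels) raises `SegmentationError` rather than returning an empty
  result.

This is rough segmentation by design: no active contours, watershed or
overlap resolution. On real smears with overlapping or poorly stained
cells it will fail in ways the synthetic validation cannot reveal (see
below).

## Feature sets

**F1 — relative nucleus size.** NC = N_area / (N_area + C_area), the
fraction of the cell occupied by the nucleus. Dimensionless, in
(0, 1]; rises strongly with dysplasia grade, which makes it the single
most discriminative feature.

**F2 — dynamic range and four moments.** Computed from the normalized
gray-level histogram p(z), z = 0..L−1 (L = 256 by default):
dr = z_max − z_min, m = Σ z p(z), σ² = Σ (z−m)² p(z),
μ₃ = Σ (z−m)³ p(z) (raw intensity³ units, not σ-normalized), and
excess kurtosis μ₄ = σ⁻⁴ Σ (z−m)⁴ p(z) − 3. A constant region has
undefined kurtosis; it is recorded as 0 so feature vectors stay
finite. F2 is computed on the nucleus and the cytoplasm separately
(10 values); a config switch (`f2_regions`) restricts it to one region.

**F3 — relative displacement.** Euclidean distance between the
cytoplasm and nucleus centroids (sub-pixel precision) divided by the
equivalent-circle diameter 2·sqrt(area/π) of the full cell region.
Translation-invariant by construction.

**F4 — Haralick features.** A single symmetric co-occurrence matrix is
accumulated over all offsets (defaults: 16 quantized gray levels,
distance 1, the four directions 0°/45°/90°/135°, each pair counted in
both directions), restricted to pixel pairs whose two endpoints both
lie inside the region mask, then normalized. The 11 statistics use
1-based gray levels (quantized bin index + 1), so the pair-sum
distribution p_{x+y} spans 2..2Ng and the pair-difference distribution
p_{x−y} spans 0..Ng−1. Conventions:

* entropies in bits (log₂), with 0·log 0 := 0;
* correlation defined as 0 when a marginal is degenerate
  (σ_x σ_y = 0, e.g. a constant region);
* sum variance is the second moment of p_{x+y} about the *sum entropy*
  — the classic reading of the "f8" that appears inside its formula;
* difference variance is the variance of the p_{x−y} distribution;
* difference entropy carries the standard leading minus sign (one
  widely circulated printing of the formula omits it), so it is
  non-negative.

**F5 — local binary patterns.** code = Σ_p s(g_p − g_c)·2^p with
s(x) = 1 for x ≥ 0: a flat patch codes to 2^P − 1 = 255, which is the
stated sign convention, kept exactly. Neighbors sit on a circle of
radius R (neighbor p at angle 2πp/P, p = 0 pointing along +columns),
sampled by bilinear interpolation; a tolerance of 1e−9 in the
comparison absorbs interpolation round-off so exactly-equal neighbors
still count as 1. Only pixels whose full neighborhood lies inside the
image contribute, and only if they are inside the region mask.
Defaults P = 8, R = 1, uniform binning (the 58 patterns with at most
two circular 0/1 transitions get their own bins, all others share
one). The full histogram is available; compact feature vectors use its
entropy (config `lbp_projection`).

**F6 — Tamura features.**

* *Coarseness*: dyadic window averages A_k over 2^k×2^k neighborhoods,
  k = 1..5, and directional differences
  E_k(r,c) = max(|A_k(r,c+2^{k−1}) − A_k(r,c−2^{k−1})|, vertical
  analogue). Averages and differences are computed only where their
  full support lies inside the region's bounding box — no padding
  convention — so scale k is valid at a pixel only with a margin of
  2^k from each border. Each pixel picks the valid scale with the
  largest E_k (first maximum on ties), and coarseness is the mean of
  2^k_best over pixels with at least one valid scale. A constant
  region therefore gives exactly 2 (all E_k = 0, tie-break to k = 1).
* *Contrast*: Fcon = σ / α₄^{1/4} with α₄ = μ₄/σ⁴ the raw fourth
  standardized moment; a constant region gives 0.
* *Directionality*: 3×3 difference operators give per-pixel gradient
  magnitude (|ΔH| + |ΔV|)/2 and orientation, binned into a 16-bin
  histogram H_D over [0, π) for pixels with magnitude ≥ 12 (intensity
  units). Peaks are strict circular local maxima above the mean bin
  height; each peak's window extends to the nearest valley on either
  side; the score is 1 − bins · n_peaks · Σ_p Σ_{φ∈w_p} (φ−φ_p)² H_D(φ),
  clipped to [0, 1] (the normalization constant and window rule are
  not standardized anywhere; these are this package's choices). No
  qualifying edge pixels → 0.

Tamura features are computed on the rectangular bounding-box crop of
the region mask rather than the exact mask, because the window
averages are rectangular by construction; for single-cell crops the
bbox is dominated by the cell, and the convention is identical between
implementation and validation oracles.

**F7 — edge orientation histogram.** Sobel gradients on the region
crop (interior pixels only); orientation arctan(G_v/G_h) mapped to
(−90°, 90°] (the H = 0 limit maps to 90°), 8 bins; only pixels whose
gradient magnitude reaches a threshold contribute (default: Otsu on
the magnitudes, so the edge set adapts to contrast). Compact vectors
use the histogram entropy. An edge-free image yields the zero
histogram and entropy 0.

The texture support region for F4–F7 defaults to the whole cell
(nucleus ∪ cytoplasm); nucleus-only or cytoplasm-only are config
options. The compact default vector has 28 columns (1 + 10 + 1 + 11 +
1 + 3 + 1). Descriptions of this feature family circulate with both
"24 features" and "23 features" totals that cannot be reconciled with
the per-set dimensionalities; the schema here is explicit and
configurable instead of guessing at an unrecoverable count.

## Classifiers

C1–C4 are SVMs (libsvm via scikit-learn), one-vs-one multiclass with
one-vs-rest-aggregated decision values exported for ROC construction:
linear; polynomial degree 2 (γ = 'scale', coef0 = 1); RBF with
exp(−‖u−v‖²/(2σ²)), σ = 10; and sigmoid tanh(γ u·v), γ = 1/n_features.
Regularization C = 1.0, configurable. C5–C7 are feed-forward networks
with logistic hidden units, softmax output, cross-entropy loss, Adam,
at most 500 epochs, seeded initialization. Hard-label ties resolve to
the lowest class id (scikit-learn's first-class convention).

Features are z-scored per column before fitting (parameters stored
with the model); kernel machines on mixed-unit features (areas,
intensities, entropies) otherwise degenerate. `scale=False` preserves
the unscaled reading; both modes exist because historical results of
this pipeline family do not state their scaling.

## Evaluation

Stratified k-fold cross-validation (default k = 10): folds depend only
on (labels, k, seed); the scaler is fitted inside each training fold,
so no statistics leak from held-out data. Held-out predictions pool
into one confusion matrix (rows = true class); precision_c =
100·TP/(TP+FP) and recall_c = 100·TP/(TP+FN) on the 0–100 scale, with
undefined precision (a class never predicted) recorded as 0 and
flagged. One-vs-rest AUC per class comes from the pooled continuous
scores via the trapezoidal rule. Stratification is a deliberate
choice: with seven classes of 70–200 samples, unstratified folds are
unstable.

`precision_recall` accepts an optional per-class `support` vector that
overrides the recall denominators. This exists for scoring published
confusion matrices whose printed rows do not sum to their stated
class totals: the reference 917-cell matrix shipped in the acceptance
script has two such rows (printed sums 240 and 160 against stated
totals 197 and 150), and the stated totals are what its published
recall ratios (e.g. 157/197) are computed from.

## Synthetic data

The generator emulates the geometry and photometry of stained
single-cell crops: bright background (230), mid-intensity cytoplasm
(135–160) and dark nucleus (50–80), both regions drawn as
low-order-Fourier perturbed ellipses (harmonics 2–4; the amplitude
models increasingly irregular nuclear outlines and grows with class
id), plus a smooth random texture field inside the cell (bilinearly
upsampled coarse noise; correlation length 3–16 px, shrinking with
severity so abnormal cells carry higher-frequency chromatin texture)
and Gaussian pixel noise (sd 3 by default).

Per-class presets fix the NC-ratio ranges
(0.04–0.08, 0.08–0.13, 0.28–0.36, 0.38–0.46, 0.48–0.56, 0.60–0.68,
0.64–0.72 for classes 1–7) and nucleus displacement ranges (up to 12 %
of the cell diameter for abnormal classes). Two structural facts are
encoded deliberately: mean NC is non-decreasing from class 1 to 7 with
the abnormal classes strictly above the squamous normals, and presets
6 and 7 overlap in NC and share intensity/texture settings, so severe
dysplasia vs carcinoma in situ is genuinely ambiguous — cross-validated
confusion concentrates in those two cells of the matrix, the same
place human graders disagree. The nucleus is drawn in the cell's own
elliptical frame so large nuclei scale with the cell; displacement is
clamped so the nucleus stays inside, and a nucleus that cannot fit
even when centered raises an error. Ground truth (`true_nc`,
`true_rd`) is measured pixel-exactly from the emitted masks, so
manifest values and mask re-measurements agree by construction.

Default problem sizes — 128×128 px frames, 70 cells per class (490
total) for end-to-end runs — keep a full pipeline execution around ten
seconds while leaving every class with enough samples for stratified
10-fold CV.

**What passing on synthetic data shows — and does not.** It shows the
pipeline is internally correct: every texture feature matches an
independent brute-force oracle, segmentation recovers known masks
(Dice = 1.0 noise-free, NC/RD within 0.005 at noise sd 5), and the
classifier separates classes whose generative parameters differ. It
does *not* show clinical performance: real Pap smears have stain
variability, debris, overlapping cells, out-of-focus regions and much
subtler class differences. Published per-class precisions on the real
917-cell benchmark (e.g. ~97 % for normal squamous but ~59 % for
severe dysplasia) cannot be reproduced or approximated from synthetic
data, and this package does not claim them.

## Numerical conventions and degenerate inputs

* Entropies in bits; 0·log 0 := 0 throughout.
* Quantization to Ng gray levels: q = ⌊z·Ng/L⌋, clipped to Ng−1.
* Constant regions: kurtosis 0, Tamura contrast 0, directionality 0,
  Haralick correlation 0, coarseness 2; constant *images* fail
  segmentation (no contrast) rather than producing empty masks.
* Dice of two empty masks is defined as 1.
* All randomness flows from explicit integer seeds (`numpy`
  default_rng; per-cell seeds derived from the master seed), and the
  full train/predict path is reproducible bit-for-bit given the same
  seed and platform.

## Known limitations

Single-cell crops only — no multi-cell scenes, overlap resolution or
whole-slide formats; no physical-unit calibration (ratios make µm/px
metadata unnecessary, though it is carried); no rotation-invariant LBP
variants, multi-scale GLCM pyramids, or Haralick features 12–14; no
hyperparameter search or class-imbalance reweighting; evaluation is
uniformly 10-fold CV even where historical tables may have used other
splits.
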