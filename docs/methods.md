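# Methods

This note documents the model implemented by `gliopix`, the choices made
where the design was genuinely open, and what the synthetic tests do and
do not demonstrate.

## Superpixel clustering (SLIC / SLIC0)

Pixels are clustered in (gray, row, col) space by localized k-means. The
distance between pixel i and cluster center j is

    D = sqrt(d_c^2 + (d_s / S)^2 * C^2)

with d_c = |I_i − I_j|, d_s the Euclidean pixel distance, S = √(N/K) the
nominal grid interval (N pixels, K requested superpixels) and C the
compactness weight (intensity units). Implementation details that pin
down the exact output:

- **Seeding.** Centers start on an n_rows × n_cols grid with
  n_rows = round(√(K·H/W)), n_cols = round(K/n_rows), so the seed count
  tracks K on any aspect ratio. Each seed moves to the lowest-gradient
  pixel of its 3×3 neighbourhood (ties keep the grid node, so this is a
  no-op on flat images).
- **Assignment.** A pixel competes only among centers whose search
  window contains it (|Δrow| ≤ S and |Δcol| ≤ S). Ties go to the
  lowest-index center. Pixels in no window (possible after centers
  drift) fall back to the nearest center by the same distance over all
  centers. These rules are frozen and verified against a per-pixel
  brute-force oracle, iteration by iteration.
- **Update.** Centers move to the mean (gray, row, col) of their
  members; empty clusters keep their previous center. 10 iterations by
  default.
- **SLIC0.** The first iteration uses C = 10. Afterwards each center's C
  is the running maximum gray distance observed among its members,
  floored at 1 intensity unit — flat regions become compact grid cells
  while high-variance regions let the boundary follow the image.
- **Connectivity.** After the final iteration, 4-connected components
  smaller than (N/K)/4 pixels are absorbed into their largest adjacent
  component and labels are renumbered in raster order, so every final
  superpixel is one 4-connected component.

## Choosing K: asymmetry descriptors and the K regressor

A healthy axial slice is nearly mirror-symmetric; tumors break the
symmetry. Two scalars summarise this:

- **Midline alignment.** Exhaustive search over integer horizontal
  shifts (±20 px) and integer rotations (±10°), maximizing the Pearson
  correlation between the left half and the mirrored right half. Ties
  prefer the smallest correction. This is a deliberately simple,
  derivative-free stand-in for model-based midsagittal detection; it is
  exact for the phantom cohort and adequate for roughly centred clinical
  slices.
- **TAR.** The aligned slice (resampled to 240×240 when needed — the
  grid assumes 15 px cells) is divided into 16×16 cells. Each left-
  hemisphere cell is correlated with its horizontally flipped right
  twin; cells with r < 0.81 are suspected tumor, and TAR = n/256 where n
  counts flagged left cells. Zero-variance handling: a pair with *both*
  cells flat (background) is symmetric by convention; a pair where only
  one side is flat (e.g. a homogeneous tumor core facing textured
  tissue) scores r = 0, i.e. asymmetric. Without the second rule a
  perfectly homogeneous lesion would be invisible to the descriptor.
- **TC.** Boundary pixels (≥ 1 of 4 neighbours outside; image border
  counts as outside) divided by area pixels of the union of flagged
  left-hemisphere cells; 0 for an empty suspected region. Only the left
  hemisphere is used so a lesion is not counted twice.

**Best-K labelling** (training only): for K ∈ {10, 20, …, 450}, SLIC0
superpixels whose overlap fraction with the ground truth exceeds 0.9 are
merged into a candidate region and its Dice recorded. The Dice–K curve
typically shows a wide near-optimal plateau; the labelled K is the
middle of the longest contiguous run within 0.01 of the maximum (first
run on ties). The middle of the plateau is the robust choice — any K on
the plateau performs almost equally, and the plateau median automates
what would otherwise be a manual pick.

**K regression**: a 5-tree random forest on inputs (TAR, TC), unlimited
depth, nodes with fewer than 5 samples are not split, bootstrap seeded.
Predictions are averaged over trees, rounded to the nearest multiple of
10 and clipped to [10, 450]. The model serialises to JSON (explicit tree
arrays), so prediction needs no fitted scikit-learn object.

## The 69-feature descriptor

Per retained superpixel (17 + 3×13 + 1 + 12 = 69):

- **17 intensity statistics** of the raw pixel values: energy, entropy,
  minimum, maximum, mean, median, range, standard deviation, variance,
  mean absolute deviation, RMS, skewness, kurtosis, uniformity, 10th and
  90th percentiles, IQR. Entropy (bits) and uniformity use a 64-bin
  histogram of the superpixel's value range; kurtosis is non-excess
  (normal = 3); skewness/kurtosis of a constant region are defined 0;
  moments use the population (n) normalisation.
- **39 Haralick texture features**: the 13 classic measures (angular
  second moment, contrast, correlation, sum of squares, inverse
  difference moment, sum average, sum variance, sum entropy, entropy,
  difference variance, difference entropy, IMC1, IMC2; the numerically
  unstable 14th is omitted) computed from symmetric co-occurrence
  matrices at offset 1 in directions {0°, 45°, 90°, 135°}, with both
  pair ends inside the superpixel. Three source images: the original
  slice (GLCM), its Roberts gradient magnitude (GLGCM) and its Prewitt
  magnitude map (GLCCM), each linearly re-quantized per superpixel to
  {8, 16, 32, 64} gray levels. The 4 directions × 4 levels are averaged,
  keeping 13 values per matrix type. Logs are base 2 with an ε = 1e−12
  guard; sum variance is centred on the sum average; a region with no
  valid pairs yields 13 zeros.
- **1 curvature feature**: mean over the superpixel of
  Curv = (f_xx·f_y² + f_yy·f_x² − 2·f_xx·f_x·f_y) / (f_x²+f_y²)^{3/2}
  with central-difference derivatives. Note the cross term uses f_xx,
  not the textbook f_xy — the implementation keeps this form
  deliberately as the method's defining formula. Pixels with
  f_x² + f_y² < 1e−8 get curvature 0 (the expression is 0/0 there).
- **12 fractal features**: the slice foreground (intensity ≥ 5) is split
  once per slice into 4 intensity channels by multi-level Otsu (3
  thresholds maximizing between-class variance; an exact-value histogram
  is used when the intensity alphabet is small, 256 bins otherwise, and
  the class rule is value ≤ threshold). Per channel ∩ superpixel: area
  (pixels), mean original brightness (0 if empty) and the box-counting
  dimension of the channel's 4-neighbour edge image inside the
  superpixel — occupied-box counts at sizes {1, 2, 4, 8, 16, 32},
  least-squares slope of log count vs log(1/size). Slices with fewer
  distinct foreground intensities than channels yield 12 zeros.

Texture and curvature maps are whole-slice operations, so a superpixel's
features depend on a one-to-two-pixel border of context; two identical
superpixels give identical features when their local context matches.

## Classification and assembly

Superpixels with mean brightness < 5 are background: excluded from the
feature table and forced non-tumor. Training superpixels are labelled
tumor when the fraction of their own pixels inside the ground truth is
≥ 0.5 (overlap fraction, not symmetric Dice — a small superpixel wholly
inside a large tumor must count as tumor). Features are z-scored with
training statistics (zero-variance columns scale by 1). The RBF-SVM's
(C, γ) pair is selected on a deterministic 7×7 logarithmic grid,
C ∈ [1e−3, 1e3], γ ∈ [1e−4, 10], by mean 5-fold stratified
cross-validated balanced accuracy (folds shuffled with the run seed;
first maximum wins), with class weights inverse to class frequency since
tumor superpixels are a small minority; the winner is refit on all
training data. The stored model is the explicit kernel expansion
(support vectors, dual coefficients, bias), so prediction is independent
of the fitting library and survives JSON round-trips bit-for-bit. The
final mask is the union of tumor-predicted superpixels.

## Evaluation

Dice 2|A∩B|/(|A|+|B|) (1 for two empty masks); Hausdorff distance as the
classic max of directed distances between 4-neighbour boundary pixel
sets, Euclidean, in pixels (not a percentile variant), NaN when a mask
is empty; sensitivity/specificity in percent with the specificity
denominator covering all ground-truth-negative pixels of the slice
including black background. Cohort tables report mean ± sample sd per
group plus an ALL row.

## Synthetic phantoms

`gliopix.synthetic` generates the study conditions for all tests:
240×240 12-bit slices with an elliptical head (tissue ≈ 600), a mirrored
smooth random texture field (sd 80), symmetric ventricle/band structures,
background 2 (< 5), and optional independent Gaussian pixel noise
(default sd 10) confined to the head. Tumor phantoms add a blob of
intensity tissue + 800 (default) whose radius (default 25 px) is
modulated by a low-order random harmonic series scaled by the
`irregularity` amplitude, strictly inside one hemisphere; the exact blob
mask is the ground truth. The mirrored texture is essential: healthy
cells must stay correlated with their mirror twins under pixel noise, as
structured brain tissue does — a texture-free phantom would decorrelate
everywhere and saturate TAR.

What phantom-based tests demonstrate: every stage's contract, exact
determinism, and that the pipeline learns and generalises on
high-contrast, well-aligned, noise-controlled inputs (held-out Dice
≈ 0.99 at the defaults). What they do not demonstrate: performance under
real T2 contrast, where edema/tissue boundaries are weak, intensity
scales vary between scanners, and the midline search must cope with
anatomy that is only approximately symmetric. Clinical-scale accuracy
claims require training and evaluation on the corresponding clinical
data.

## Problem sizes and numerical choices

The shipped experiments use a cohort of 20 phantoms (16 train / 4 test),
a 200-sample synthetic descriptor set (160/40) for the K-regressor
recovery check, and the full K grid {10..450}; these sizes keep a full
training run at a few minutes on one CPU while exercising every code
path. Tolerances and tie rules not already stated above: SLIC ties go to
the lowest center index; the plateau rule uses ε = 0.01 and the lower
middle for even-length plateaus; K rounding uses round-half-up;
histogram quantization maps the region maximum into the top level.

## Known limitations

- Single-channel T2 only; no multi-sequence fusion, no 3D supervoxels.
- The midline search assumes the head is roughly centred and the
  asymmetry is lesion-driven; strong anatomical asymmetry inflates TAR.
- Bilateral (mirror-symmetric) lesions defeat the asymmetry descriptors
  by construction.
- The 0.81 similarity threshold and the 0.5 annotation threshold are
  fixed operating points, exposed in `PipelineConfig` but not learned.
- Hyperparameter search is an exhaustive log-grid; with larger feature
  tables a sequential optimizer would reach the same operating point
  faster.
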