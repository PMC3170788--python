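# Methods

## Model

A sample is an (image, caption) pair with a modality label. The classifier
is a precomputed-kernel SVM over a fused similarity measure built from M
independent feature channels, followed by an optional local-refinement stage.

**Feature extraction.** Images are decoded to integer RGB/grayscale arrays
and bilinearly resized to a common square size before any extraction, so the
block grids and histogram scales of different images are comparable. RGB is
reduced to luminance (0.299R + 0.587G + 0.114B, rounded) for the gray, edge,
variance and SIFT channels. Every count histogram is normalized to sum to 1;
a zero-count histogram (e.g. the edge histogram of a constant image) is kept
as the all-zero vector rather than raising, so degenerate images flow through
the pipeline. Binning is half-open with the last bin closed throughout.

- *Gray histogram*: counts of intensities in `n_bins` equal-width bins
  (default 256, i.e. one bin per level).
- *Color histogram*: each pixel quantized to the joint bin
  (⌊rk/256⌋, ⌊gm/256⌋, ⌊bl/256⌋), flattened red-major; default k=m=l=4
  (64 bins). The quantization used in the original experiments of this method
  family is not documented; 4×4×4 is a conventional coarse choice.
- *Edge histogram*: central-difference gradients with replicate borders;
  per 4×4 block, gradient magnitude accumulated into 20 equal orientation
  bins over [0°, 360°); each block normalized independently so every block
  contributes equal mass regardless of local contrast; concatenated row-major
  (320 dims). The 20-bin orientation semantics is this package's explicit
  choice; the descriptor family it follows only fixes "20 bins per block,
  gradient-weighted".
- *Variance histogram*: population variance of the (2r+1)² patch around every
  interior pixel (default r=2), binned into 32 equal bins over [0, 255²/4]
  (the largest variance attainable by values bounded in [0, 255]), overflow
  clamped into the last bin.
- *Bag of visual words*: 16×16 patches sampled on a stride-8 grid; per patch
  a 128-dim SIFT descriptor (4×4 spatial cells × 8 orientation bins, hard
  assignment, contributions weighted by gradient magnitude times a Gaussian
  window with σ = side/2, unit L2 norm; an all-gradient-zero patch maps to
  the zero vector, which makes the descriptor exactly invariant to positive
  affine intensity maps a·I+b). Training-fold descriptors are clustered with
  seeded k-means++ (Euclidean, single init, Lloyd iterations); the BoW
  histogram counts nearest-center assignments (ties to the lowest center
  index) divided by the patch count. The codebook is always built from
  training data only.
- *Textual feature*: captions tokenized into lowercase alphanumeric runs; the
  feature is a binary vector over an ordered keyword vocabulary (default: a
  bundled 90-term reconstruction of a modality-indicative vocabulary —
  modality names, acronyms, common caption words; the historical 90-word list
  was never published, so any vocabulary file can be substituted). Matching
  is whole-token; multi-word entries must appear as consecutive tokens. The
  vector is deliberately not normalized to sum 1 — it is a presence
  indicator, and the kernel normalization absorbs its scale.

**Kernel fusion (equal contribution).** For feature m, pairwise distances
S_m use χ² (default), L1 or L2. χ² is Σ(x−y)²/(x+y) with 0/0 terms defined
as 0 and without the conventional ½ factor — the normalizer cancels constant
factors, so this choice is inconsequential. The per-feature normalizer

    γ_m = (1/N²) Σ_{i,j} S_m[i,j]

is the mean over all N² ordered training pairs, diagonal included. By
construction the normalized distances S_m/γ_m average to exactly 1 for every
feature — that identity is the testable content of "each feature contributes
equally" and is asserted in the test suite. The per-feature RBF kernels
exp(−S_m/γ_m) are averaged elementwise into the fused kernel (a weighted-sum
hook exists but no weighting is recommended). Test-time kernels reuse the
training γ_m; recomputing it on test data would put train and test kernels
on different scales and leak test statistics. γ = 0 (all samples identical)
falls back to 1 with a warning.

**Classification and refinement.** The global classifier is a one-vs-one SVM
(`SVC(kernel="precomputed")`, default C = 1) on the fused train kernel. Each
configured confusion group (defaults: {CT, MR, XR}, {NM, PET}, {GX, PX})
gets a local SVM trained on the group's training samples only, with γ_m
recomputed on that subset. Recomputing γ on the subset is the point of the
stage: globally, γ_m is dominated by large between-group distances, so
within-group kernel contrast is compressed toward 1 and the global SVM
under-resolves the group; locally, γ_m equals the within-group mean distance
and the contrast is restored. Refinement is a single pass keyed on the
global *prediction*: a sample globally predicted inside a group is re-decided
by that group's local model; everything else is untouched (so refinement is
a projection on non-group predictions). Groups must be disjoint, which makes
iteration unnecessary. A group with fewer than two classes present in the
training data is skipped with a warning.

## Evaluation drivers

Cross-validation uses stratified folds (shuffled with the config seed);
per-class counts at desk scale are small enough that unstratified folds
would be noisy. Per fold, the codebook, the γ_m and all SVMs are trained on
the training folds only; per-sample quantities that cannot leak (single-image
histograms, SIFT descriptors, caption keyword vectors) are computed once and
reused across folds. Three conditions are reported: all visual features;
visual + textual; visual + textual with refinement. Aggregate accuracy is
micro (correct/total); confusion matrices are row-normalized percentages
(per-class recall on the diagonal), with zero-support rows reported as NaN.
The fixed-split driver selects a per-class random training subset and tests
on the remainder; the metric-comparison driver tabulates single-feature
accuracy under L1/L2/χ² on one such split.

## Synthetic data

The generator emulates exactly the separability structure the features
measure: per class a base gray level (drawn once per image from N(mean, std)),
an oriented sinusoidal grating (smooth gradients at a controlled orientation —
chosen over step edges so the edge signal is robust to the gradient-operator
choice), per-pixel Gaussian noise (drives local variance), an RGB tint, and
caption keywords emitted independently with a class probability amid
non-vocabulary filler words. Randomness is counter-based: (master seed,
class index, item index, stream) seeds an independent generator per image
and caption, so any subset regenerates identically. Classes declared as a
confusable pair share all visual parameters *by construction* — any
systematic visual separability of such a pair indicates leakage, not signal.

Three canonical scenarios (64×64 images) are frozen in the package:

- `well_separated_spec` — 5 classes × 40 images separated on every channel,
  keyword probability 1. Used for the cross-validation recovery study.
- `visual_twin_spec` — 5 classes × 40 with NM/PET visually identical and
  caption-distinguishable (keyword probability 0.9, so text is informative
  but not an oracle). Measures the multimodal gain.
- `weak_pair_spec` — 4 classes × 30; NM/PET differ only in noise std (20 vs
  21) under a shared base-level jitter (std 12) that makes the gray channel
  misleading, while CT (noise 2) and US (noise 80) sit far away and inflate
  the global γ_m. Captions carry no signal. This is the regime the local
  classifiers exist for: across splits the global classifier resolves the
  pair at roughly 70–85% while the refined predictions reach the mid-90s.

What passing these studies shows: the formulas, the leakage-free protocol,
and the *mechanisms* (text rescues visual twins; local γ recomputation
rescues weakly-contrasted pairs) all work end to end. What it does not show:
accuracy on real medical images, whose within-class variability, class
imbalance, caption noise and inter-feature correlations the generator makes
no attempt to model. Reported accuracies on synthetic data are properties of
the scenarios, not forecasts.

## Problem sizes and numerical choices

Desk-scale defaults used by the studies and tests: images generated at
64×64 and standardized at 64 (the configurable default for real data is
256), codebook of 50 centers (default 200 for real data; both are
configurable), patch 16/stride 8, SVM C = 1. The acceptance script's three
studies complete in well under a minute on one CPU at these sizes.

Ties and degeneracies are all resolved deterministically: nearest-center
ties to the lowest index, one-vs-one voting ties by sklearn's deterministic
decision-value rule, orientation/bin boundary values by half-open binning.
Fixed seeds make codebooks, splits and models bit-reproducible; the model
archive is text-only (features, γ, codebook, vocabulary, config, support
coefficients) and is reloaded by deterministic refit rather than by
deserializing learner internals.

## Known limitations

- The edge-histogram bin semantics and the SIFT Gaussian σ are this
  package's documented choices where the descriptor family leaves them open;
  they are not claimed to replicate any particular historical binary.
- Confusion groups are configuration, not discovery: the package does not
  derive groups from a validation confusion matrix.
- The weighted-kernel hook is provided but unvalidated; equal contribution
  is the supported fusion.
- Single-process execution; no attempt at parallel determinism guarantees.
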