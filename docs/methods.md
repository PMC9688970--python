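# Methods

## The estimators

`mventropy` quantifies the spatial irregularity of a multichannel image
I ∈ ℝ^{H×W×q} (RGB being the motivating case, q = 3) with two multivariate
template-matching entropies.

**Embedding.** Given per-channel embedding sizes M = [m₁, …, m_q] and
n = max(M), every anchor (i, j) on the grid i = 0..H−n−1, j = 0..W−n−1
(N_m = (H−n)(W−n) anchors) yields a *composite delay vector*: the
concatenation, channel by channel, of the m_k×m_k patch of channel k
anchored at (i, j), each patch read row-major.  The composite dimension is
m = Σ m_k².  Vectors are compared with the Chebyshev (maximum-norm)
distance over all their elements, channels pooled — this is what makes the
measure multivariate: a single excursion in any channel breaks a match.

**Sample variant (MSampEnRGB).** B^m(r) is the mean frequency with which a
vector finds another within tolerance r (self-matches excluded).  The
embedding is then extended: from [m₁, …, m_k, …, m_q] the system may evolve
to any [m₁, …, m_k+1, …, m_q], giving q·N_m extended vectors.  Because the
anchor grid is built from n rather than n−1, the enlarged (m_k+1)-patch
always fits inside the image for every base anchor, so all q·N_m extended
vectors exist; no anchors are dropped.  Each extended vector is compared
against the N_m−1 other vectors sharing its extended embedding shape (see
below), B^{m+1}(r) is the mean match frequency over all q·N_m of them, and

    MSampEnRGB(I, M, r) = −ln( B^{m+1}(r) / B^m(r) ).

When either frequency is zero the estimate is undefined; the library
returns a flagged NaN result, never an exception, so multiscale profiles
can record gaps.

**Fuzzy variant (MFuzEnRGB).** The Heaviside match is replaced by the
graded similarity D = exp(−dˢ/r) averaged over all ordered pairs (self
excluded) at both dimensions; the entropy is the negative log of the ratio
of the two mean similarities.  Since D > 0 the estimate is defined wherever
the input is valid — the practical reason to prefer it on highly irregular
data.

With q = 1 both estimators reduce to the bi-dimensional (grayscale) sample
and fuzzy entropies, and the test suite checks that reduction against
independently coded single-channel implementations.

### Conventions the definitions leave open

* **Counting denominators.** The printed constants of the source
  formulation (1/(N_m−n−1) at the base dimension, 1/(q(N_m−n)−1) extended)
  carry the 1-D notation where N−n counts vectors; in the image formulation
  the vector counts are N_m and q·N_m.  The default mode
  `normalization="consistent"` therefore divides each per-vector count by
  the true number of comparison partners (N_m−1, group size −1), keeping
  every frequency in [0, 1]; `normalization="literal"` applies the printed
  constants verbatim.  For a fixed image shape the two modes differ by a
  constant offset ln c in the entropy (tested), so no qualitative result
  depends on the choice.
* **Extended-dimension comparison scope.** The distance is defined in
  image coordinates — the maximum over corresponding patch positions and
  channels — which only exists between composites of identical structure.
  Extended vectors are therefore compared within the group sharing their
  extended embedding shape: one group of N_m vectors per extension channel.
  (The 1-D multivariate method pools all extended vectors, which works
  there because every 1-D extension has length m+1; in 2-D the extension
  adds 2m_k+1 elements and changes the patch structure, so pooling would
  compare misaligned elements and make the estimate depend on the
  arbitrary patch read-out order, destroying its transpose and
  channel-permutation invariance.)
* **Tolerance scale.** r is absolute, in the intensity units of the input.
  The kernel neither checks nor enforces normalization; the pipeline
  z-normalizes images first (see below), which makes r a fraction of the
  image's standard deviation.
* **Pair enumeration.** Ordered pairs with (i,j) ≠ (a,b) at both
  dimensions, for both measures.

## Pre-processing

Images are center-cropped (offset ⌊(src−target)/2⌋ on each axis — fixed
for bit-reproducibility) and z-normalized to mean 0, standard deviation 1
(population convention, ddof = 0).  Normalization is pooled over all pixels
and channels by default: a per-channel normalization would rescale each
channel separately and distort the cross-channel Chebyshev comparisons the
multivariate distance relies on.  `per_channel=True` is available.
Grayscale conversion for univariate baselines uses the de-facto luma
weights 0.2989/0.5870/0.1140 (note they sum to 0.9999, so pure white maps
to 1 only to 1e-4).  Conversion happens before normalization.

## Multiscale profiles

Coarse-graining at scale factor τ replaces each non-overlapping τ×τ block
(per channel, starting at the top-left) by its mean; trailing rows/columns
that do not fill a block are discarded rather than padded (padding injects
artificial regularity).  No re-normalization is applied after
coarse-graining and r stays fixed across scales: re-normalizing would erase
the variance-reduction signature by which white-noise entropy falls with τ
while correlated texture holds its level.  The profile over τ = 1..τ_max
(default 10) is the feature vector for classification; undefined scales
are flagged, not dropped, so profiles across an image set stay aligned.

## MIX synthetic benchmarks

MIX(p) mixes a deterministic sine template (period 12, amplitude 1 per
axis; 2-D template sin(2πi/12)+sin(2πj/12)) with Uniform[−3, 3] noise,
pixel-wise, with noise probability p — a ground-truth irregularity dial
from perfectly periodic (p = 0) to pure white noise (p = 1).  Each channel
is an independent MIX process by default (mask Z and noise Y drawn per
channel); `shared_mask=True` ties the corrupted-pixel mask across channels
while keeping noise values channel-specific.  Determinism contract: one
seeded generator per call, Z drawn before Y, each in one C-order block.

The validation protocol z-normalizes each generated image before entropy,
matching the pipeline applied to real images and making r comparable
across p (the raw MIX variance grows from 1 at p = 0 to 3 at p = 1).

**What the generator does not emulate:** spatially correlated noise,
illumination/pose variation, inter-channel correlation structure of
natural textures, or class overlap.  Passing the synthetic benchmark shows
the estimator orders controlled irregularity correctly and that the
pipeline is leak-free — not that any particular accuracy will transfer to
real histology or material textures.

### Parameter behavior worth knowing

* At a tight tolerance (r = 0.02 on normalized images) the hard-threshold
  sample measure finds no extended-dimension matches once noise dominates
  (p ≳ 0.4 at 100×100, M=[2,2,2]) and becomes undefined — the classic
  sample-entropy failure mode.  The MIX sweeps therefore run the sample
  measure at r = 1, where it is defined over the whole p range, and the
  fuzzy measure at r = 0.02.
* The fuzzy measure at r = 0.02 rises strictly with p through p = 0.8 and
  saturates between p = 0.8 and p = 1 on normalized images (normalization
  contracts pure-noise distances the most); the tests assert strict
  ordering through p = 0.8 and a high-above-mid check at p = 1.
* Larger embeddings separate consecutive irregularity levels better:
  M=[2,2,2] yields a wider mean consecutive-p gap than M=[1,1,1] for both
  measures (asserted in the acceptance tests, reported by the acceptance
  script).

## Classification harness

Each image's multiscale profile is one feature row.  Rows containing an
undefined value are excluded and counted (imputation would manufacture
texture information).  Splits are stratified random 75/25, repeated 5
times; rows are addressed through a canonical (label, id) ordering so
results do not depend on table row order.  The classifier is an SVM (RBF
kernel, C = 1, gamma = "scale" by default; linear kernel exposed), with
feature standardization fitted on the training fold only.  Accuracy is
100·correct/total per split, reported per split and as the arithmetic
mean.

## Numerical and performance choices

* The optimized kernels enumerate unordered vector pairs in numba-compiled
  loops: an early-exit scan for hard counting (a pair stops as soon as the
  running maximum exceeds r) and a block-transposed vectorizable scan for
  the fuzzy similarity, which needs completed maxima.  A combined scan
  (`msampen_mfuzen_rgb`) accumulates both statistics in one pass — the MIX
  sweeps use it with r_sample = 1 and r_fuzzy = 0.02.
* Fuzzy similarities below exp(−55) ≈ 1e−24 are skipped.  The truncation
  is exactly inactive whenever the data diameter is ≤ (55r)^{1/s} (all
  oracle fixtures, which use raw [0, 1] intensities), and otherwise
  contributes at most n_pairs·exp(−55) ≈ 1e−15 absolute error to sums whose
  retained terms are many orders larger.  Consequence: on data whose
  *every* pair distance exceeds the cutoff the fuzzy sums underflow to
  zero and the result is flagged undefined rather than reporting a value
  dominated by sub-1e−24 similarities.
* A deliberately naive pure-Python implementation of both estimators
  (`mventropy.reference`) is kept in the package and pinned to the fast
  path at 1e−10 on a seeded fixture grid.
* Problem sizes in the test-suite sweeps (10 seeds, 100×100 MIX images for
  the response and multiscale checks; 100 images at 50×50 for the
  benchmark; 3 seeds in the acceptance script) were chosen to give stable
  seed-means while keeping a full run in the minutes range on one core.

## Symmetries

Both measures are exactly invariant (to floating-point identity) under
intensity shifts, transposition of all channels, and — with equal per-channel
embedding sizes — channel permutation: these transforms map every composite
vector onto a composite vector of the transformed image, and the
maximum-norm distance ignores within-patch element order.  180°-rotation
invariance does *not* hold exactly: the anchor grid reserves its spare
row/column on the high-index side only, so rotation shifts the base patch
set by one anchor, and rotation maps an extended composite's (m_k+1)-patch
and m-patches to different anchors, altering the extended vector set.  The
resulting discrepancy is a boundary term (≈1e−3 on 14×12 fixtures) that
shrinks with image size.

## Known limitations

* Cost is quadratic in the number of anchors; 100×100 with M=[2,2,2] takes
  seconds per image, megapixel images are out of reach without subsampling
  (the pipeline's center-crop exists precisely for this).
* Only the RGB/grayscale color spaces are covered; no HSV/Lab.
* The hard-threshold measure's undefined region is inherent, not a bug;
  use the fuzzy variant or a wider r there.
* No composite/refined multiscale variants; block-mean coarse-graining
  only.
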