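# Methods

## Problem and model

A lysine site is represented by its 49-residue sequence window (±24
residues around the modified K) and carries a non-empty subset of four
modification types: acetyl, crotonyl, methyl, succinyl. Of the 15 possible
subsets, 11 are admissible categories (A, C, M, S, AC, AM, AS, CM, ACM,
ACS, ACMS); records with any of the other 4 combinations are excluded
with a logged count. Duplicate windows are merged by unioning their
modification sets; if the union is inadmissible the window is dropped.
Windows overhanging a terminus are padded with `X`, a neutral symbol:
`X`-containing triads contribute to no frequency count and encode to
feature 0, so padding is information-free by construction.

## MLPSTAAP encoding

The encoder scores each of the 46 overlapping triads of the K-less
48-residue context by a class-contrast frequency. For category *t*,
`F_t[i, j]` is the fraction of that category's training contexts whose
triad at position *j* has row index *i* (8000 rows, one per triad over
the 20-letter alphabet). `FF_t` is computed identically over the pooled
contexts of the other 10 categories (each window counted once). The
propensity matrix is `F_MLPSTAAP = mean_t(F_t) − mean_t(FF_t)`; its
entries lie in [−1, 1].

Design choices:

- **Fitting population.** Propensity matrices are fitted on the training
  split only and frozen into the model artifact; encoding test data with
  class-frequency statistics derived from the test data itself would leak
  label information.
- **Denominators.** Per-class frequencies divide by the number of
  sequences even when `X` padding removes countable triads, so columns
  touching padded positions sum to less than 1. On padding-free data every
  column of `F` and `FF` sums to 1 and of `F_MLPSTAAP` to 0 (asserted at
  tolerance 1e−9 in the tests).
- **Complement definition.** `FF_t` uses the multiset union of the other
  categories' windows, computed as (total counts − own counts) /
  (total size − own size); this is exactly the pooled-complement
  frequency without re-counting.
- Matrices are stored dense (8000 × 46 ≈ 0.37 M doubles each); sparsity
  is not worth the indirection at this scale.

## ClusterCentroids undersampling

Only the majority category is resampled by default. Its *N* feature
vectors are clustered with mini-batch k-means into
`k = max(1, round(ratio·N))` clusters (round half-up); the centroids
replace the original samples as synthetic majority prototypes carrying
the majority label. `ratio` is the post-/pre-sampling count ratio,
default 0.1.

Mini-batch k-means: k initial centers drawn uniformly from the data
without replacement; per iteration a batch of `b` points (default 1024,
capped at n) is sampled without replacement, assigned to the nearest
center by Euclidean distance, and every touched center is reset to the
mean of its assigned batch members. `T = 100` iterations by default.
With `b ≥ n` each iteration is exactly one full-batch Lloyd step, which
is how the implementation is validated against the scikit-learn Lloyd
oracle started from the same initial centers. A center that receives no
batch points in an iteration is simply left in place; a cluster that is
empty under the final full-data assignment is re-seeded to a random data
point and assignments are recomputed once. Because centroids are convex
combinations of data points, every synthetic prototype lies inside the
majority class's bounding box (property-tested).

A practical consequence worth knowing: centroid averaging smooths rare
feature patterns out of the majority class. Majority windows that happen
to carry a minority-like signature are diluted into their cluster means,
which is one of the two mechanisms (with the reduced class prior) by
which undersampling shifts decisions toward minority labels.

## Classifier

The 46-vector is treated as a 1-channel signal. Four blocks of
convolution (kernel 3, padding 1; channels 16, 32, 64, 128) → ReLU →
max-pool (width 2, stride 2, trailing remainder dropped) reduce the
length 46 → 23 → 11 → 5 → 2; the flattened 256 values feed one dense
layer with four sigmoid outputs. Loss is the mean binary cross-entropy
over samples and labels, with probabilities clamped to
[1e−7, 1 − 1e−7]. Training uses Adam (lr 1e−3), mini-batches (default
64), and records the mean per-batch loss per epoch plus the
full-dataset loss before any update. Implementation is plain numpy with
explicit backpropagation; all randomness derives from one seed, so
training is bit-reproducible on a fixed platform.

Numerical/initialization choices: conv weights are He-normal; the output
layer starts at zero, so an untrained network outputs exactly 0.5 for
every label and the initial loss is exactly ln 2 regardless of the label
distribution — a useful self-check. Zero-initializing the last layer
delays gradient flow to the conv stack by one optimizer step, which is
immaterial at these sizes. Prediction thresholds each probability at 0.5,
boundary inclusive; an all-zero prediction is reported as "no
modification predicted" rather than being forced to the argmax label.

The layer counts are fixed by the architecture; kernel sizes, channel
widths, optimizer and schedule are conventional defaults exposed in
`ClassifierConfig`, not claims.

## Evaluation

Chou's five set-based metrics with M = 4. A sample with an empty
predicted set would make the Aiming denominator 0; such samples
contribute 0 to Aiming and Accuracy, follow the formulas elsewhere, and
are counted in the report (`n_empty_predictions`). Absolute-True ≤
Accuracy holds per sample and is asserted on every report; the
per-category Absolute-True values, weighted by category size, average
exactly to the global Absolute-True (tested as an identity). Categories
absent from an evaluation set are reported as missing, not as 0.

Cross-validation is stratified by the 11 categories; categories with
fewer members than folds are spread best-effort. Within each fold the
propensity model is fitted and the majority class undersampled on the
training folds only. The harness reports the pooled metrics over all
held-out predictions (equivalent to the fold mean for equal fold sizes
and more stable for categories with a handful of members) together with
per-fold reports. The ratio sweep repeats the CV per undersampling ratio
and tabulates per-category Absolute-True in percent (two decimals), rows
= ratios, columns = the 11 category labels.

## Synthetic benchmark

The generator emulates the one statistical structure the encoder assumes:
class-specific positional triad biases. Each window is 48 i.i.d.
background residues (uniform over the 20 letters by default) with the
central K inserted; per planted motif, a 3-residue word overwrites a
fixed context position with a given probability. Windows flow through the
production FASTA/TSV entry points.

The default imbalanced benchmark (`default_imbalanced_spec`):

- category counts scale the reference training inventory
  9279:710:600:454:561:252:360:88:153:454:73 by 1/10 with a floor of 8
  per category (so 5-fold stratification stays possible); the majority
  category remains >71% of samples at any scale;
- each modification **type** has one fully penetrant determinant — a
  homotriad at a fixed context position (W³@6, Y³@17, H³@28, F³@39) — and
  a category plants the determinants of its constituent types, the way a
  multiply modified site carries each modification's sequence context.
  The four positions are spaced 11 apart because the classifier's four
  stride-2 pooling stages alias nearby positions: two distinct motifs
  planted 4 positions apart deep in the window map to identical deep
  representations and become inseparable regardless of sampling — an
  architecture artifact, not the imbalance effect under study;
- every window additionally carries the determinant of each type it does
  *not* bear with probability 0.03 ("decoys"). Real sequence windows
  contain determinant-like words without the modification; without this
  overlap the classes are perfectly separable, imbalance is harmless, and
  the undersampling question evaporates. The decoy rate bounds the
  majority category's exact-match ceiling after undersampling near
  1 − (1 − 0.03)³ ≈ 0.91 while giving the majority's decoy mass enough
  weight at full ratio to suppress minority flags — the regime the method
  is designed for.

What the benchmark does **not** emulate: realistic proteome composition,
homology structure, positional dependence between residues, or weak
distributed (non-motif) signals. Passing the synthetic experiments shows
the pipeline recovers planted positional triad signal under the reference
imbalance; it says nothing about accuracy on real modification data.

Observed behavior at the default desk scale (5 seeds × 5-fold CV,
classifier at 12 epochs, batch 32 — sizes chosen as the package's
standard experiment configuration): pooled Absolute-True ≈ 0.92 at ratio
0.1 with the minority-category mean rising from ≈ 0.68 (ratio 1.0) to
≈ 0.94 (ratio 0.1) while the majority category declines slightly — the
qualitative ratio effect the sampler exists to produce. These numbers are
recomputed, not quoted, by `tests/test_acceptance.py`.

## Determinism and provenance

One global seed drives every stage; the CLI derives stage seeds at fixed
offsets (split +1, sampler +2, classifier +3) and writes a provenance
JSON (config echo, derived seeds, sizes, timings) next to each artifact.
The model artifact is a single `.npz` holding the propensity matrices,
CNN weights, configuration and an encoder fingerprint (SHA-256 prefix of
the propensity matrix) that is verified on load, so a prediction is
reproducible end-to-end from the artifact alone.

## Known limitations

- Homology-aware redundancy reduction (CD-HIT-style clustering) is not
  reimplemented; the pipeline deduplicates exact windows only and expects
  pre-reduced FASTA when homology inflation matters.
- The per-sequence denominator convention makes padded columns sum below
  1; an alternative (dividing by countable triads) would renormalize
  boundary columns but change the feature scale near termini.
- The CNN's pooling hierarchy discards fine positional information deep
  in the window (see the motif-spacing note above); signals closer than
  ~4 positions apart in the deep layers are indistinguishable.
- Mini-batch centroid updates use the plain batch mean of currently
  assigned members, not count-decayed running means; with small batches
  centroids therefore jitter rather than converge, which is acceptable
  for prototype generation but not for density estimation.
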