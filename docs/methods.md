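# Methods

## Reduced alphabets

The six canonical alphabets are stored verbatim from the published
two-property table (non-empty column cells, top-to-bottom order defining
class indices 0..K−1), not re-derived by intersecting the one-property
table. The reason is that the underlying per-property classification is
internally inconsistent: the solvent-solubility row lists S, T and C in two
classes and omits D, N, Q and R entirely, so no intersection rule can
reproduce the published columns. `build_alphabet` still offers the
intersection construction for user-supplied properties, with two explicit
conventions: a letter claimed by more than one cell goes to the first cell
in (i, j) order (the published SS_CP column lists L twice; first occurrence
keeps the printed class count of 6), and letters covered by neither
property are appended as a single overflow class so the result is always a
total partition. Note that intersecting the built-in surface-tension and
charged-polarity properties yields 7 classes, whereas the published ST_CP
column has 8 (it splits H into its own class); the published column wins
for the canonical alphabet.

Non-standard residue codes (B, J, O, U, X, Z) have no class and are dropped
with a warning before reduction; a sequence empty after sanitization is an
error.

## Features

RTC is normalized by the window count L−2, making it a probability vector
over the K³ reduced tripeptides; coordinates are ordered lexicographically
by (x, y, z) class indices and labelled `x-y-z`, which fixes the feature
coordinate system bit-for-bit. The PSSM parser consumes the PSI-BLAST
`-out_ascii_pssm` layout and keeps only the first 20 numeric columns — the
log-odds block — because the logistic squashing presumes signed scores
centered near zero; the weighted-percentage block would saturate it. The
matrix is stored L×20 in file row order. The 20-dim summary is the
column-wise mean of the squashed scores, hence invariant to row
permutation and strictly inside (0, 1).

PCA (scikit-learn, full SVD) reduces RTCP to 80 dimensions by default.
Component signs are fixed so each axis's largest-magnitude loading is
positive, making projections deterministic across fits. During
cross-validation the reducer is fit on the k−1 training folds only
(`pca_scope="fold"`), so no variance structure leaks from held-out data; a
`global` scope is available for comparison.

## Classifier

The network is five 1-D convolutional layers (32 filters each, kernel 3,
stride 2) with batch normalization and ReLU after each, max-pools (size 2,
stride 2) after the second and fourth convolutions, then fully connected
64 → 1 with a sigmoid output, trained with Adam on binary cross-entropy.
The learning rate starts at 1e−3 and is divided by 10 every 100 epochs;
the default budget is 1000 epochs, and the tests and acceptance runs use
60 epochs, at which the synthetic study conditions are already fit. The
compact preset replaces the stack with four convolutions (16, 16, 32, 32
filters) and fully connected 13 → 2 softmax.

Choices the architecture description leaves open, and how they were fixed:

- **Kernel size 3** — the smallest standard odd kernel sensible for an
  80-length input under stride 2 with two pools; configurable.
- **'Same' padding for convolutions** — with valid padding, five stride-2
  convolutions plus two pools cannot fit an 80-length input (the feature
  map collapses below the kernel length by the fifth layer). Same padding
  is the common framework default and keeps the published depth viable.
  `conv_output_length` documents the valid-convolution count
  floor((L−F)/S)+1; the bare ratio (L−F)/S misses the window anchored at
  position 0 and can be fractional.
- **Pool placement after conv 2 and conv 4, FC width 64, batch size 32** —
  unstated in the source architecture; all are configuration fields.
- **Single-sigmoid head** for the main preset, two-unit softmax retained
  only for the compact preset.

Everything (forward, backward, Adam, batch-norm running statistics) is
plain numpy, single-threaded; with a fixed seed, training histories are
reproducible to the last bit. The minimal input length for the default
geometry is 39 (below that, the second pool has nothing to pool), so
feeding it PCA widths much smaller than 80 is rejected with a clear error;
`--pca-dim 0` disables PCA when raw features are preferred.

## Evaluation

TP/FP/TN/FN are stored as counts (the metric formulas are scale-invariant).
Degenerate denominators — no predicted positives, a single-class fold, a
zero factor under the MCC root — yield 0 and are flagged in the bundle
instead of raising, so fold aggregation stays total. F-score is
(1+β²)·Pre·Sens / (β²·(Pre+Sens)) with β=1 by default, the harmonic mean of
precision and sensitivity. ROC curves enumerate every distinct score as a
threshold with tied scores sharing a point, and AUC is the trapezoid area;
both identities — MCC as the Pearson correlation of the label vectors and
AUC as the normalized Mann–Whitney U — are enforced in tests against
scipy/scikit-learn.

Stratified folds come from a seeded shuffle and are persisted in the CV
report. The stable-misclassification analysis fixes the folds once, then
retrains the classifier with fresh initialization seeds n_models times
(default 100); a sample mispredicted strictly more than the threshold
(default 50) is flagged as a stable false positive or false negative
depending on its true label. Re-seeding on fixed folds (rather than
re-splitting) was chosen so the counts are attributable to model
stochasticity, not fold luck.

## Synthetic data

The generator emulates exactly the statistical structure the features
consume, by design at the reduced-alphabet level so RTC is a sufficient
statistic for the class: each class draws reduced-symbol sequences from a
first-order Markov chain, the two K×K transition matrices being a shared
Dirichlet-drawn base with a seeded ~30% of entries multiplied by
(1 ± signal_strength) and rows renormalized; symbols are back-translated to
a uniform residue of their class. PSSM scores are integer-rounded
Normal(0, 2) draws — mimicking the signed, near-zero-centered log-odds the
logistic squashing expects — with `pssm_shift` added to a seeded fifth of
the columns for the positive class. Defaults (200 per class, lengths
50–250, ST_SS alphabet, signal 0.5, shift 1.0) are the package's study
conditions throughout tests and the acceptance script.

What the generator does **not** emulate: real transporter domain
architecture (Walker-A/LSGGQ motifs), alignment-derived profile structure
(position correlations, gap effects), sequence redundancy, or class
imbalance. Passing tests therefore demonstrate that the pipeline recovers
class signal expressed through reduced-tripeptide usage and profile column
shifts — not that it attains any particular accuracy on real proteins.

## Problem sizes

Tests and the acceptance script use 5-fold cross-validation on 400
synthetic proteins, 60-epoch network training, and a 10-seed null
calibration (4000 held-out predictions), sizes at which the SVM and the
network both saturate the separable conditions while the zero-signal mean
accuracy stays within the 99% binomial band around 0.5.

## Known limitations

- The canonical alphabets are frozen constants; "repairing" the
  inconsistent solvent-solubility property to make intersections reproduce
  them is deliberately out of scope.
- Whether the original profile feature used log-odds or weighted
  percentages is not recorded anywhere; this implementation commits to
  log-odds for the reason above.
- The numpy network is CPU-only and meant for hundreds-to-thousands of
  532-dim inputs, not for large-scale training.
- The ASCII PSSM reader supports exactly the PSI-BLAST dialect described;
  other profile formats are out of scope.
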