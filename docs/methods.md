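# Methods

## Network construction

Each subject is represented by per-region samples of gray-matter voxel
values. The regional probability density is estimated by Gaussian-kernel KDE
with Silverman's rule-of-thumb bandwidth (h = (3n/4)^(−1/5)·sd), evaluated
on one grid per subject: N equally spaced points spanning all of the
subject's samples padded by three times the largest per-region bandwidth.
Sharing the grid across regions makes every pairwise divergence well defined
on a common support. Defaults and their rationale:

- **N = 128 grid points** (configurable). Smooth unimodal densities are
  resolved far below the KDE's own statistical noise at this N; doubling to
  256 changes similarity entries by < 0.01 on smooth synthetic data (tested).
- **Discrete-density convention.** KDE values at the grid points are floored
  at 1e−12 and renormalised to sum to one, and the symmetrised KL divergence
  is evaluated as a plain sum over the N points with natural logarithms. The
  flooring prevents log(0) for effectively disjoint supports; the floor
  guarantees similarities stay strictly positive, so all matrix entries lie
  in (0, 1].
- **Constant samples** (zero variance) fall back to a kernel of width 1e−3
  of the grid range; a subject whose every region is the same constant is a
  degenerate-input error.
- **Diagonal and symmetry.** Only the upper triangle is computed and
  mirrored; x_pp = 1 is kept inside the feature vectors (the feature vector
  of region p ranges over all M regions, including itself).
- **Region order** is ascending numeric atlas label after exclusions,
  everywhere. With a 116-label atlas and the Vermis labels 108–115 excluded,
  M = 108.

## Classifier

Two dot-product self-attention layers (queries, keys, values are linear
maps of the region feature vectors; coefficients are the row-wise softmax of
Q_p·K_q/√d_K), each followed by Leaky ReLU (slope 1e−2) and layer
normalisation; embeddings are 32-dimensional. Head counts of 1, 2, 4, 8 and
layer counts 1–5 are configurable; with multiple heads the embedding is
split evenly, per-head coefficient maps are averaged (preserving
row-stochasticity) and outputs concatenated, so the parameter count does not
depend on the head count. Region embeddings are mean-pooled into one vector
per subject, then linear(32→32) → ReLU → batch-norm → linear(32→1) →
sigmoid. Training minimises binary cross-entropy with mini-batch Adam.

Choices that the architecture description leaves open:

- **Pooling.** Mean over the M region outputs. It matches a 32-vector input
  to the linear head and is permutation-invariant over regions.
- **Initialisation.** Glorot-uniform, seeded; training is bit-reproducible
  given a config seed.
- **Binary head.** A single sigmoid logit with BCE (not a 2-way softmax).
- **Tie-break.** Probability exactly at the decision threshold counts as
  positive (ASD).
- **Batch-norm** uses batch statistics during training and running
  statistics in evaluation mode, so inference is deterministic.

The default `ModelConfig` reproduces the full-scale recipe: learning rate
6e−6, batch 32, weight decay 0.01, 300 epochs, two single-head layers. Those
values are appropriate for cohorts of roughly a thousand subjects with 108
regions. Desk-scale synthetic studies (tens of subjects, 10–20 regions) use
learning rate 1e−2, 150 epochs and **weight decay 0**: at this scale the
loss saturates within tens of epochs, after which Adam's L2 term — acting on
the attention projections, whose loss-gradients are second-order small —
dominates and contracts W_Q and W_K toward zero, collapsing every attention
map to exactly uniform and destroying the biomarker signal. The autodiff
engine is a compact numpy reverse-mode implementation whose gradients are
verified against central finite differences in the test suite.

## Biomarker mapping

The coefficient α_pq weighs region q's value vector in region p's output, so
large coefficients mark contributing (source) regions. Per subject, the
per-layer maps are averaged into one fused map; fused maps are averaged over
a chosen subject group (all, all correctly classified, true negatives or
true positives). Entries above mean + 3·SD of the group map are reported;
statistics use all M² entries with the population SD (the diagonal can be
excluded via a flag). A constant map yields an empty report, not an error.
For synthetic cohorts, recovery is scored as the fraction of ground-truth
effect regions among the top-k regions ranked by their maximal column
coefficient.

A known limitation, measured on synthetic cohorts: dot-product attention
ranks columns largely by feature-vector geometry (regions whose similarity
profiles have large norm attract attention regardless of class), and the
classification loss exerts only weak pressure to concentrate attention on
class-informative regions — the value pathway can separate the classes on
its own, because a distributed effect shifts components of *every* region's
feature vector. On 40-subject cohorts with a 1-sd shift in 5 of 20 regions,
top-8 recovery averages ≈ 0.5 against a chance level of 0.4, and this was
stable across learning rates, epoch counts, cohort sizes (40–60), fusion
filters and multi-restart ensembling. Attention-magnitude biomarker maps
from small cohorts should therefore be read as exploratory; the package
reports them faithfully rather than sharpening them post hoc.

## Evaluation

Accuracy, sensitivity, specificity and F1 are computed from confusion counts
with ASD = 1 the positive class; ratios with zero denominators are reported
as absent rather than NaN. AUC uses trapezoidal integration with midrank tie
handling (equivalent to the normalised Mann–Whitney U; verified against
brute-force pairwise comparison). Cross-validation is seeded stratified
k-fold (default k = 5), retraining from scratch per fold with a
fold-derived seed.

The permutation test follows the label-flip design: each permutation flips
round(0.2·n) randomly chosen labels and re-runs the identical stratified-CV
procedure (retraining per permutation; a fixed-model re-scoring mode exists
behind a flag). The p-value uses the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n_perm), which is never exactly zero. A
`fast` flag caps training epochs for permutation-scale reruns.

## Synthetic cohorts

The generator emulates only what the network construction consumes: an
integer atlas volume whose labels occupy contiguous blobs (Voronoi cells of
Lloyd-balanced seeded centroids inside a one-voxel background shell,
sentinel −1), and per-region Gaussian voxel-value samples (optional
two-component mixture), clipped at zero. Region base means are drawn once
per cohort from [0.4, 0.8] with sd 0.1 — overlapping but distinguishable
regional distributions, so similarity matrices span (0, 1) rather than
degenerating to all-high or all-floor values; each subject perturbs every
regional mean by N(0, 0.05·sd) so within-group networks differ. Cases
additionally receive the configured effect (additive mean shift and/or
multiplicative spread change) in the designated effect regions. With the
null effect (shift 0, scale 1) case and control generators are the same
process, verified by distribution-equality tests. Everything is driven by
`numpy` SeedSequence spawning: identical seeds give bit-identical cohorts.

What the generator does not emulate: scanner physics, registration error,
site effects, cortical geometry, spatial voxel correlation within a region,
or non-Gaussian tails of real gray-matter distributions. Passing tests
demonstrate the machinery is correct and calibrated, not that real-data
effect sizes behave like synthetic ones.

## Reference validation studies

The quantities in `scripts/acceptance.py` come from fixed desk-scale study
designs chosen to run in minutes on one CPU: effect cohorts of 40 subjects
(20/20) with 20 regions, 200 voxels per region and a 1.0·sd shift in
regions {2, 5, 9, 13, 17}, averaged over 5 seeds; null cohorts of the same
size (accuracy averaged over the same 5 seeds, since a single 40-subject
draw has sd ≈ 0.1); and permutation calibration on 20-subject, 10-region
null cohorts with 99 permutations and reduced-epoch training, 20
repetitions. All randomness derives from the `--seed` argument.
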