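# Methods

## The model

`LANDMarkClassifier` is an ensemble of decision trees whose node splitting
rules are *learned multivariate classifiers* rather than axis-aligned
thresholds.  At each internal node a pool of candidate models is fitted to
the node's samples and each candidate's predicted labels define a partition
of the node; the partition's Shannon information gain (in bits) judges the
candidate.  Among candidates whose gain ties the maximum within
`gain_epsilon = 1e-9`, one is chosen uniformly at random.  A node becomes a
leaf when it is pure, smaller than `min_samples_split` (default 2 — trees
grow to purity; the strong per-node learners self-limit depth), at the
optional `max_depth`, or when no candidate achieves positive gain.
Prediction averages leaf class distributions over trees; ties in the argmax
go to the first class in sorted order.

### Candidate pool (per node with *n* samples, *d* features)

| family          | features   | tuned (n > 6)                           | fixed (n <= 6)        |
|-----------------|------------|------------------------------------------|-----------------------|
| logistic (L2, lbfgs)      | subset | C in logspace(1e-4, 1e4), 5-fold CV | C = 1                 |
| logistic (L1, liblinear)  | full   | same                                 | C = 1                 |
| linear SVM (liblinear)    | subset | C in {1e-3 ... 1e2}, 5-fold CV      | C = 1                 |
| SGD, L2 penalty           | subset | alpha in {1e-3 ... 1e2} x loss {hinge, modified Huber} | alpha = 1, random loss |
| SGD, elastic-net          | full   | same                                 | alpha = 1, random loss |
| ridge (GCV)               | subset | alpha in logspace(1e-3, 1e4) by generalized CV | not offered (n <= 6) |
| neural (two-branch)       | subset | — (fixed architecture)               | offered only when n > 32 |

All linear models use `max_iter = 2000`; non-convergence keeps the fitted
state and logs a debug message.  Cross-validated selection scores candidates
by mean per-class recall over stratified folds; the fold count shrinks from
5 down to the smallest class size, and below 2 usable folds the fixed
defaults apply.  Ties resolve to the first (smallest) grid value.  The
logistic C-grid uses 10 logarithmically spaced points across the prescribed
1e-4..1e4 range — a package constant; finer grids measurably slow every
node without changing selections on the small nodes this model targets.

Each "subset" candidate draws its own random feature subset of size
`ceil(max_features_fraction * d)` — different models see different views
of the node; nodes with fewer than 4 features expose the full feature set
to every family.  The default fraction is 0.4, where
generalization plateaus on the synthetic benchmark; `"sqrt"` is available
as the conventional forest baseline.

### Random linear oracle

The oracle is a random hyperplane: two distinct training rows are drawn
without replacement and samples split by the sign of
`(b - a) . (x - (a + b)/2)` (points exactly on the hyperplane go to the
positive side).  With `use_oracle=True` (default) it joins the candidate
pool at every node (`oracle_mode="candidate"`) and competes on information
gain like any other splitter — so it is kept only where a random cut
happens to align with class structure, which is why enabling it barely
moves headline scores while still diversifying trees.
`oracle_mode="root"` instead pre-partitions each tree's root with it
unconditionally (the classic random-linear-oracle ensemble design); each
half is then modelled independently.  At the few-dozen-sample problems this
package targets, the mandatory root split costs a consistent ~0.05-0.08
balanced accuracy by halving the data every model sees, which is the reason
it is not the default.  If ten draws fail to find two distinct row vectors
the oracle is unavailable at that node.  `oracle_probability` optionally
applies mandatory oracles at random nodes.

### Neural splitter

The non-linear candidate joins (a) a dense branch, hidden widths
256/128/64/48/24, mish activations, alpha-dropout rate 0.2 after the first
three layers, and (b) a random-Fourier-features projection of the input to
24 dimensions (unit-Gaussian frequencies, fixed per node) followed by dense
layers 24/24/16; the concatenated outputs feed a softmax over the node's
classes.  Training: categorical cross-entropy, Adam at learning rate 0.001,
batch size 32, a 90/10 train/validation split, at most 300 epochs with
early stopping once the validation loss has failed to improve by more than
1e-4 for 40 consecutive epochs (final weights kept).  It is implemented
directly over numpy with explicit backpropagation and competes only at
nodes with more than 32 samples.

### Randomness and diversity

Per-tree child seeds come from a spawned `SeedSequence`, so a fitted
ensemble is bit-reproducible given `random_state` and trees are
independently buildable.  Diversity between trees comes from the oracle,
the per-node feature subsets, random model initializations/loss choices and
the random tie-breaks among equivalent-gain candidates.  Two additional
resampling levels exist but default to **off**: `bootstrap` (tree-level
bagging) and `bootstrap_candidates` (fitting each candidate on a bootstrap
resample of its node, with gain still judged on the full node).  With
training sets of a few dozen samples both measurably weaken individual
trees and drag benchmark scores well below the regime the diagnostics
describe (strong, low-diversity trees); they remain available as options.

## Decision-space diagnostics

The proximity of two samples is the fraction of trees in which they share a
terminal leaf (diagonal 1 by construction); the dissimilarity is
`sqrt(1 - p)`.  Principal coordinates analysis uses classical scaling:
double-center `-D^2/2`, eigendecompose, keep positive-eigenvalue axes, and
report explained-variance ratios over the positive eigenvalues only (no
Lingoes/Cailliez correction — matching the per-axis reporting style the
diagnostics are read with).  Kappa-error diagrams place one point per
unordered tree pair at (Cohen's kappa of their hard predictions, mean of
their two error rates); when both raters are constant, kappa is defined as
1 on exact agreement and 0 otherwise.

## Evaluation statistics

`balanced_accuracy` implements the max-marginal variant used throughout the
benchmark harness: mean over classes of `c_ii / max(row sum, column sum)`,
with classes absent from both margins excluded.  It equals mean per-class
recall exactly when the confusion matrix has matching row and column sums;
the conventional mean-recall variant is exposed separately
(`mean_recall_accuracy`).  Note the variant is *not* chance-centred at 0.5:
a constant predictor on balanced two-class data scores 0.25.
Feature-recovery MCC is the Matthews correlation of the 2x2 table induced
by a selected feature set against the planted truth, with the
zero-denominator -> 0 convention.

## Synthetic data generator

The generator emulates a two-condition presence-absence ASV experiment with
a planted ground truth:

- **Baseline.** Per-feature occurrence probabilities `p_O` are either
  estimated from a real presence-absence table (occurrence frequency
  clipped to `[1/(2n), 1 - 1/(2n)]` so log-odds stay finite) or drawn from
  a Beta(0.6, 3.4) occupancy profile truncated below at 2/24.  The
  truncation mirrors the provenance of real baselines: a table filtered to
  features seen in at least 2 of 24 samples cannot yield occurrence
  probabilities far below 2/24.  The truncated profile has mean occupancy
  ~0.22 — many rare features, few ubiquitous ones.
- **Design.** 48 samples: 24 controls drawn feature-wise Bernoulli(p_O)
  (or verbatim real rows via `control_rows`), and 24 treatments that are a
  *copy* of the control block in which only `n_perturbed` randomly chosen
  columns (25, 50 or 75) are replaced by fresh Bernoulli(q) draws.  The
  perturbed probability solves the log-odds shift
  `logit(q) = logit(p_O) + log(p_N)` in closed form,
  `q = p_O p_N / (1 - p_O + p_O p_N)`, with `p_N` drawn per feature from
  {0.1, 0.125, 0.25, 0.5, 2, 4, 8, 10}.  Because unperturbed columns are
  exact copies, they carry no group signal whatsoever — the detection
  problem is confined to the planted columns, which is what makes
  feature-recovery MCC in the 0.7-0.8 range attainable at these sample
  sizes.  An `independent_treatment` flag instead redraws the whole
  treatment block Bernoulli(p_O); that much noisier reading caps even an
  ideal frequency-difference selector near MCC 0.4 and is retained only for
  comparison.
- **Noise.** Afterwards `ceil(0.05 d)` randomly chosen columns are permuted
  across all 48 samples, decoupling them from the labels.
- **Truth.** The mask of perturbed features and the applied `p_N` values
  are recorded for MCC scoring.

What the generator does *not* model: read counts, compositional closure,
sequencing error, taxonomic structure, and between-sample correlation.
Passing benchmarks on this generator therefore show that the pipeline
recovers planted occurrence-probability shifts at realistic sparsity and
sample size — not that it handles abundance effects or phylogenetically
structured signal in real surveys.

2-D toy generators (two interleaved Archimedean spirals; concentric rings
via scikit-learn's `make_circles`) probe non-linear decision boundaries.
The exact parameters of their published counterparts are not available;
this package uses 1.75-turn spirals with Gaussian noise 0.25 and a 0.45
ring-radius factor as representative settings of this benchmark family.

## Feature-selection pipeline

RFE refits `model_factory()` and drops the lowest-importance
`ceil(step_fraction * remaining)` features (default step 0.1, never
crossing below `n_keep`, default 100).  Importance sources: native
impurity/gain importances where a model exposes them, else mean
|coefficient|; for the oblique ensemble itself, each node's achieved gain
(weighted by its sample share) is distributed over the node's feature
subset proportionally to absolute splitter coefficients — uniformly for
oracle and neural nodes — and summed over trees.  Kernel-Shapley
importances (mean |attribution| over explained samples) implement
model-agnostic scoring: exact coalition enumeration when `2^M - 2` fits the
sampling budget, otherwise Shapley-kernel-weighted coalition sampling
(default budget 768 per explained sample) solved as a constrained weighted
least squares, so attributions plus the base value reproduce the model
output exactly.  The half-split consistency experiment perturbs the sample
space by stratified halving (split *i* seeded with *i*), fits full and
RFE-reduced models per half, assigns eliminated features importance exactly
0, and reports Spearman's rho between the halves' importance ranks and the
Jaccard distance between selected panels.

## Problem sizes used by the shipped checks

The full-scale study design is 30 replicate datasets per scenario with
64-tree ensembles.  The shipped test-suite and `scripts/acceptance.py`
scale this down for a single CPU as the package's own verification sizes:
300-feature baselines, 16-tree oracle ensembles with the neural splitter
off, 12 replicates per scenario in the acceptance script (8 in the test
suite); the 2-D non-linearity benchmark uses 120 training / 400 test
points with 4-tree ensembles.  At these sizes the benchmark means carry
replicate-to-replicate spreads comparable to the full design's reported
standard deviations, which is the tolerance the checks use.

## Known limitations

- Training cost is dominated by per-node cross-validated grid searches;
  wall-clock scales roughly with (nodes) x (grid size) and becomes heavy
  for thousands of samples.  Trees are independently buildable from child
  seeds if a user wants process-level parallelism.
- The max-marginal balanced accuracy is reported for comparability with the
  benchmark convention; its values are not directly comparable to the
  common mean-recall definition on imbalanced confusion matrices.
- BIOM support is read-only (HDF5 2.1 layout); TSV is the canonical
  round-trip format.
- Kernel-Shapley sampling noise at large M is bounded by the coalition
  budget; the exact path engages automatically only for M <= ~10 at the
  default budget.
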