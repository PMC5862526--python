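# Methods

## Quantitation model

Ct (cycle threshold) is the number of PCR cycles needed for a
transcript's signal to reach detection; it is a log-scale quantity, and
the package assumes 100% primer efficiency throughout, i.e. one cycle
equals exactly one log2 unit (one doubling) of expression.

A *sample* is one (mouse, structure) RNA preparation. Normalization
proceeds in two steps:

* **ΔCt** subtracts a per-sample reference from each gene's Ct. The
  default reference is the *global-normalization* value — the
  arithmetic mean Ct of eight stably expressed reference genes (*Dkk3,
  Tagln3, Gars, Scrn1, Rpl36al, Mcfd2, Psma7, Hpcla4*) — which averages
  out the error a single housekeeping gene would inject. A
  single-gene mode (e.g. GAPDH) is also provided.
* **ΔΔCt** subtracts the mean ΔCt of the sample's control cohort,
  computed per (structure, gene). Averaging on the ΔCt scale means the
  control baseline is a geometric mean of expression; consequently the
  geometric mean of fold inductions within any control cohort is
  exactly 1 (a checked invariant). Fold induction is `2^-ΔΔCt`.

Control membership is encoded in the `control_group` column of the Ct
table: each row names the experience label of the cohort it is
normalized against, and control animals name their own cohort.

An alternative reading — averaging the controls on the linear fold
scale — is exposed in configuration but is not the default.

## Feature space and decoder

Each mouse is represented by the induction of 5 marker genes (*Arc,
Egr2, Egr4, Fos, Fosb*) in 5 structures (limbic cortex, nucleus
accumbens, dorsal striatum, amygdala, lateral hypothalamus): 25
(gene, structure) features. Features are stored as log2 fold by
default: induction and repression become symmetric and Euclidean
distances are not dominated by the largest inductions. Linear fold is
a first-class alternative (`transform="linear"`).

The decoder is k-nearest-neighbor with k = 1 over Euclidean distance,
with no feature standardization (a z-scoring flag exists for
sensitivity analysis). Evaluation is leave-one-out: each mouse is
classified from all the others. Determinism is guaranteed by explicit
tie-breaking: equal distances resolve to the lowest row index; for
k > 1 a tied vote resolves to the nearest tied-class member. Exact
ties have measure zero on continuous data but occur in degenerate test
fixtures, and reproducibility requires a fixed rule.

Feature-space reductions (`collapse_features`) probe where the signal
lives: per-gene sub-matrices (one gene across structures), per-structure
sub-matrices, or spatial averaging of each gene over structures.

## Marker ranking

Candidate genes are scored on the grid of (structure, experience)
*cells*, control cohorts excluded. `frequency_count` (#) counts cells
whose replicate-mean fold induction reaches two-fold (inclusive ≥ by
default). `avg_variance` (S²) is the mean over cells of the
within-cell variance (ddof = 1) of induction. The combined rank is the
rank of (descending-frequency rank + ascending-variance rank), ties
broken lexicographically by gene name; rank-sum is the minimal
interpretation of "combined ranking".

Two genuinely open definitional choices are exposed as options rather
than fixed: the scale on which S² is computed (linear fold — default —
or log2 fold) and whether all cells or only induced cells enter the
average (`cells="all"|"induced"`). Note a structural consequence of
the linear-fold default: a gene's variance grows with its induction, so
in a small candidate pool a consistently silent gene can out-rank an
induced one on the combined criterion. The frequency ranking alone
separates induced from silent genes cleanly, and the synthetic tests
assert exactly that.

## Permutation test

The null distribution of decoder accuracy is built by shuffling the
mouse-to-experience assignment N times (uniformly at random, sampled
with replacement from the permutation group; enumerated exhaustively
when n! ≤ N) and re-running the identical LOO evaluation on each
shuffle. The primary p-value uses the strict inequality

    p = (1/N) · Σ_i 1[acc(S_i) > acc(S)]

so a decoder that beats every shuffle reports p = 0. Because LOO
accuracy is discrete (multiples of 1/n), ties between the observed and
null accuracies are frequent, and the strict fraction is systematically
*below* uniform under the null. `PermutationResult` therefore also
reports the tie-splitting mid-p, `(#{>} + ½·#{=})/N`, which is the
calibrated quantity for a discrete statistic (measured on zero-effect
data: Kolmogorov–Smirnov against U(0,1) gives p ≈ 0.6 for the mid-p
versus ≈ 7·10⁻⁴ for the strict fraction), and the conventional add-one
bound `(r+1)/(N+1)` with `r = #{≥}`, since a reported 0 is a statement
about the N draws rather than the population.

With k = 1 the nearest-neighbor graph does not depend on labels, so
each shuffle only relabels a fixed graph; the whole null distribution
costs one distance matrix plus O(N·n) comparisons. This fast path is
verified against per-shuffle re-decoding in the tests.

## Feature selection

**Random-KNN support.** Feature subsets are sampled with a uniform
random size (default 1..25) and uniform features without replacement;
for each subset the LOO k-NN accuracy is computed. The support of
feature f is the mean accuracy of the M sampled classifiers containing
f. Sampling matches exhaustive lattice enumeration when the lattice is
small (a checked property). Default ensemble 10⁴ subsets; the
full-scale setting of 10⁶ is configurable but changes rankings little
beyond 10⁴ at these dimensions.

**Random-forest MDG.** Each of n_trees (default 10³, full-scale 10⁵)
CART trees draws a feature subset of uniform random size and a
bootstrap resample of mice, and is grown with Gini splits
(scikit-learn trees under the hood). A feature's importance is its
impurity decrease — `(w·i(node) − w_L·i(L) − w_R·i(R))/w_root`, summed
over the nodes it splits within a tree — averaged over the trees whose
subset contained it. A balanced two-class root split into pure halves
scores exactly 0.5, the hand-checkable anchor. Selected subsets are
evaluated by a pruned tree (depth ≤ 4, ≥ 3 mice per leaf) under
stratified 10-fold cross-validation; classes smaller than the fold
count trigger a fallback to unstratified folds with a warning.

**Descriptive CART.** An unconstrained binary tree grown to purity
with entropy-based information gain (bits). Candidate thresholds are
midpoints between consecutive sorted unique values; score ties break to
the lower feature index, then the lower threshold. Indistinguishable
feature vectors with conflicting labels become a majority-labeled leaf
flagged impure. Rendered as indented text plus a node-table CSV.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: cohorts
of mice, one labeled experience each, with class-specific mean log2
fold inductions per (gene, structure) feature and Gaussian within-class
noise on the log2 scale (Gaussian Ct error and Gaussian log2 fold error
are the same model). Defaults are the study conditions: 10 experience
classes, 5 genes × 5 structures, 5 mice per class, effects of 3 log2
units, noise_sd 0.5. Ct-level output adds reference genes (technical
noise only, default ct_noise_sd 0.25 cycles — a realistic scale for
SYBR qPCR replicates), baseline Cts (24 for markers, 20 for reference
genes), and matched control cohorts of the same size.

Two signal layouts are provided. `default_config` gives each class a
disjoint pair of informative features (20 informative, 5 silent) —
maximally separable classes for decoding tests. `sparse_signature_config`
uses 5 informative "diagonal" features whose 10 unordered pairs define
the 10 classes — few enough informative features to fit a 25-feature
top quartile, the substrate for feature-recovery tests; per-feature
effect sizes can be graded to impose a true importance ordering.

A property worth flagging: with one control cohort per experience, all
treated mice of a class share their cohort's finite-sample
normalization error, which imprints a class-correlated offset on the
folds *even at zero effect* — the permutation test then correctly
reports significant decodability of the cohort structure. A zero-effect
calibration design must therefore normalize everything against a single
shared baseline cohort, which is what `null_config` does
(`shared_control=True`). This is a real caveat of per-group ΔΔCt
normalization, not an artifact of the simulator.

What the generator does not emulate: induction time-courses,
habituation trajectories across repeated days, cell-type heterogeneity,
plate/batch effects, or non-Gaussian outliers. Passing tests establish
correctness of the computations under the stated noise model, not
robustness to those real-data phenomena.

## Problem sizes and numerics

The test suite and the acceptance script run the ensembles at 10⁴
Random-KNN subsets, 10³ forest trees and 10³–10⁴ permutations — sizes
at which rankings and p-values are stable across seeds at these data
dimensions (tested: Kendall τ ≥ 0.6 among top features across seeds).
All randomness flows from a single run seed through named per-stage
`numpy.random.SeedSequence` streams; identical config + seed gives
bit-identical tables. Distances are computed as exact squared
Euclidean sums (no BLAS expansion tricks), so decoder results are
reproducible across platforms at float64 precision.

## Limitations

* Published-data reproduction requires the study's deposited per-mouse
  expression table, which is not redistributed here; the suite marks
  that check as failing until `data/supplementary_features.csv` is
  supplied (schema in `tests/test_acceptance.py`). Consequently the
  printed-value ambiguities (linear-vs-log2 decoding transform, the
  exact S² definition) cannot be resolved empirically and both
  candidate definitions remain options.
* The "modified" Gini gain mentioned for the forest procedure is
  implemented as the standard size-weighted impurity decrease.
* k-fold tree evaluation on 5-mice classes with k = 10 necessarily
  breaks stratification; results carry a warning.
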