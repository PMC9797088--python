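# Methods

## The model being interpreted, and what this package computes

A fitted tree ensemble (random forest or boosted trees, classification or
regression) partitions the feature space along its root-to-leaf paths.  Each
path is a *decision* `D = (r_D, ŷ_D)`: a conjunction rule `r_D` with at most
one condition per feature, and a constant prediction `ŷ_D` on the rule's
sample support `S_D = {i : r_D(x_i) = 1}`.  forestnet flattens the ensemble
into this set of decisions, simplifies it, and summarizes how features and
pairs of features contribute to the ensemble's predictions.

For a sample subset `S` the error function is

* regression: `α(S, ŷ) = mean_{i∈S} (y_i − ŷ)²`,
* binary classification: `α(S, ŷ) = mean_{i∈S} (1 − ŷ^{y_i}(1−ŷ)^{1−y_i})`,
  which reduces to the misclassification fraction when `ŷ ∈ {0,1}`.

The quantities, with `ȳ` the working-sample mean:

* **decision importance** `I_D = (1 − α(S_D, ŷ_D)/α(S_D, ȳ)) · |S_D|`,
  multiplied by the decision's multiplicity.  The bracket is R² for
  regression and Cohen's κ for classification, evaluated on the support.
* **decision-wise feature importance**
  `δ_D^j = α(S_D, ŷ_{D_j^rm}) − α(S_D, ŷ_D)`, where `D_j^rm` removes the
  condition on feature `j` and its prediction is recomputed on the widened
  support.  Both errors are evaluated on the *original* support `S_D` —
  only the prediction moves.  This is easy to get wrong and is pinned by
  the brute-force oracle tests.
* **decision-wise interaction importance** `δ_D^{jk} = sqrt(δ_D^j δ_D^k)`,
  set to 0 when the product is negative (a harmful variable earns no
  interaction credit).
* **direction indicator** `d_D^j ∈ {−1, +1}`: +1 when the rule admits
  predominantly large values of the feature.  Concretely: for discrete or
  discretized features, +1 iff the mean rank of the admitted levels is at
  least the mean rank of all observed levels; for raw numeric intervals,
  +1 iff the mean feature value inside the admitted region is at least the
  overall mean.  Ties break to +1.  This rank rule is this package's
  definition (exposed as `direction_indicator`); it behaves as expected on
  ordered level sets and is deterministic.
* **influences** `γ_D^j = d_D^j (ŷ_D − ŷ_{D_j^rm})` and
  `γ_D^{jk} = ((d_D^j + d_D^k)/2)(ŷ_D − ŷ_{D_{jk}^rm})`; the pair influence
  is exactly 0 when the two directions disagree.
* **aggregates** `F_j = Σ_D δ_D^j I_D` (same for pairs),
  `Γ_j = Σ_{D∈D_j} γ_D^j I_D / Σ_{D∈D_j} I_D` over the decisions where the
  feature is active, and the pair-direction sign
  `η_{jk} = sign(Σ d_D^j d_D^k I_D)` rendered as solid (+) or dashed (−)
  edges.

Predictions of the initial decisions are recomputed from the data rather
than read from leaf values, so that every modified rule (removal,
complement, pruning, discretization) stays under one estimator.  Complement
decisions (`D_j^c`, the rule with the acted condition complemented) are
implemented and exported but enter no aggregate.

### Two influence granularities

Network nodes are (feature, admitted level-set) pseudo-features such as
`V1__High` or `Group=a`.  A node's influence is the importance-weighted mean
of the *raw* prediction shift `ŷ_D − ŷ_rm`: membership in the admitted set
plays the role of the "high" side, so the `Low` node of a positively
associated feature is correctly rendered negative.  Variable-level `Γ_j`
(reported in `feature_metrics`) uses the direction indicator as defined
above, so that e.g. a feature whose low values predict the negative class
comes out positive at the variable level.  Edge influence and η always use
the direction indicators.

## Regularization

1. **Discretization** (default `K = 2` levels, labels Low…High).
   Breakpoints are empirical quantiles at `i/K` ("data" method) or a
   frequency-weighted 1-d k-means over the model's split thresholds with
   `K−1` centers ("rf-thresholds").  Every numeric condition is rewritten to
   the set of levels whose observations *majority-satisfy* it (strict
   majority); a condition admitting every level is dropped from its rule; an
   empty admitted set drops the decision.  Features with fewer distinct
   values than `K` are kept unsplit with a warning.
2. **Pruning** (default relative tolerance 0.05).  Iteratively remove the
   variable with the smallest error increase while
   `(α(S_D, ŷ_rm) − α(S_D, ŷ_D)) / max(α(S_D, ŷ_D), 1e−6) ≤ tolerance`,
   recomputing support/prediction/error after each removal.  A decision
   pruned down to an empty rule is the trivial decision: it is kept through
   grouping (so Σ multiplicity is conserved) but carries no features and is
   ignored by stability selection and all aggregates.
3. **Duplicate grouping.** After every decision-wise step, identical
   canonical rules (features sorted, level sets sorted, half-open intervals
   `[lo, hi)`) collapse into one decision whose multiplicity accumulates;
   the decision importance is weighted by that multiplicity.

## Stability selection

With parameters `B` (resamples, default 10), `π_thr ∈ (0.5, 1]` (default
0.7), `α > 0` (default 1; the expected number of false discoveries) and a
resample fraction (default 1/2):

* each bootstrap draws `⌈fraction·n⌉` samples with replacement (the
  prediction model is never refitted);
* decision-wise regularization is re-run *inside* each resample: decisions
  with empty resample support are dropped, pruning runs against the
  resample, duplicates regroup.  This matters: a noise condition's survival
  under pruning is a resample-level fluctuation, so it reappears
  inconsistently across bootstraps and falls out of the stable set — this
  is the mechanism that controls false positives.  Discretization
  breakpoints stay fixed at their full-data values: quantiles are
  low-variance statistics and fixed breakpoints keep rule identity
  comparable across resamples;
* all decision metrics are recomputed per resample (with `ȳ` the resample
  mean), decisions are ranked by importance, and the top
  `q = ⌊max{1, (2π_thr − 1)·α·d}⌋` recorded, where `d` is the average
  decision count across resamples (the product is rounded at the 9th
  decimal before flooring so binary representation noise cannot shift it);
  ties at the boundary break by (importance, support size, rule string);
* decisions in the top-`q` of at least `π_thr·B` resamples are retained;
  every decision's metrics are averaged over the resamples where it was
  *present*, and the final feature/interaction aggregates are recomputed
  from those averages.

Bootstraps run sequentially; each draws its indices from a generator seeded
by (master seed, bootstrap index), so results are independent of execution
order and of how work would be scheduled in parallel.

## Visualization and network reduction

The importance/influence table lists, per feature, the importance summed
over its level-sets and, per (feature, level), the influence averaged over
the stable decisions whose admitted set contains that level; levels
appearing in no stable decision are flagged absent (rendered blank).
The decision network connects pseudo-feature nodes by edges for every pair
co-active with positive interaction importance in at least one stable
decision.  `reduce_network` removes lowest-importance edges until every
connected component has diameter ≤ `max_path` (default 3).  Because edge
removal can both split components and lengthen detours, the criterion is
not monotone in the removal threshold; the implementation scans candidate
thresholds (−∞ plus the distinct importances) in ascending order and
returns the first qualifying subgraph — the least destructive cut.
Exports report importances both raw and max-normalized to [0, 1].

## The synthetic benchmark

`simulate_fsd(n, r, seed)` draws 12 independent `N(0.5, 1)` predictors
`V1..V12` and a group factor uniform over {a, b, c, d}; the response is set
by a fixed rule table: in group a, the response is +1 iff V1 and V2 share
their sign (all four sign cells covered); in group b, +1 iff `V3 > 0`; in
group c only the same-sign V4/V5 cells are covered (+1 both positive, −1
both non-positive); in group d only the opposite-sign V6/V7 cells
(`V6>0 & V7≤0 → +1`, `V6≤0 & V7>0 → −1`).  Cells covered by no rule get a
uniform ±1 label — any deterministic fill would inject undocumented signal.
Each label's sign then flips independently with probability `r`, and ±1 is
encoded as {0, 1}.  The generator emulates the idealized study conditions —
independent Gaussian predictors with a known sparse rule structure; it does
not reproduce the compositionality, sparsity or feature dependence of real
sequencing data, so passing tests demonstrate correctness of the machinery,
not performance on real metagenomes.

The ground-truth network derived from the table has 11 nodes (a–d, V1–V7)
and 10 edges (pairs co-occurring in a rule).  Node signs: +1 if the
variable's high side predicts the positive class in every rule it enters
(V3, V4, V5, V6), −1 if always the negative class (V7), "depends"
otherwise (V1, V2 and all group levels, whose effect is context-dependent).

**Evaluation** collapses predicted level-set nodes to distinct
variable-level entities (group levels keep their identity; duplicates
merge with importances summed) and counts TP/FP/FN nodes and edges,
precision, recall, and an importance-weighted precision (the share of
predicted importance sitting on true entities).  An optional alias map
renames predicted labels onto truth labels with each truth entity
creditable once.  TP/FP curves re-build the network at every distinct
bootstrap selection probability; the random baseline averages 1000 random
orderings of the predicted edges (its expectation is hypergeometric,
`E[TP at k] = k·T/N`, which the tests verify).

## Test-harness forests

The evaluation harness fits scikit-learn random forests with the group
factor one-hot encoded and the dummy splits folded back into category-set
conditions (`fold_one_hot`); sklearn's `x ≤ t` splits are read under the
package's strict-less convention, which is exact on training data up to
measure-zero midpoint ties.  Harness defaults: `max_depth=4` (one level
more than the deepest generating rule after one-hot folding),
`min_samples_leaf=5`, `max_features=0.5` — the widened candidate set
compensates for the dilution of a single factor across four dummies
relative to factor-aware learners whose subset splits treat the factor as
one candidate.  Deeper default-style forests recover the same true edges
but accumulate more unprunable noise conditions, degrading the importance
share of true edges.

## Problem sizes used by tests and the acceptance script

The formula oracle runs 200 random mini-ensembles (≤5 decisions, ≤4
features, n ≤ 50).  Perfect-model recovery uses one dataset of n = 1000 at
r = 0.05.  The null control runs 20 independent permutation runs (response
permuted within group, 200-tree forests, default stability parameters) and
expects ≤ ~1 stable decision on average.  End-to-end recovery runs 10
datasets of n = 1000 at r = 0.05 with 500-tree forests and K = 2, B = 10,
α = 5.  These sizes are the package's chosen benchmark conditions; the
whole suite runs on one CPU in a few minutes.

## Numerical choices and degenerate inputs

* `α(S_D, ȳ) = 0` (constant response on the support) defines `I_D = 0`
  rather than raising; empty supports drop the decision at extraction.
* Feature deltas with magnitude below 1e−12 are treated as exact zeros
  before interaction products are formed — `sqrt` would otherwise amplify
  representation noise of an exactly-zero delta into ~1e−9 artifacts.
* Numeric conditions are half-open `[lo, hi)`; strict-less splits generate
  exactly these, and intersection and complementation stay closed-form.
  The complement of a two-sided interval is represented as a negated
  condition (used only by complement decisions).
* Classification responses are {0, 1} internally with the positive class
  mapped to 1; multi-class responses reduce one-versus-all.

## Known limitations

* Binary classification and regression only; multi-class is handled by
  one-versus-all reduction at data loading.
* No missing-data handling (surrogate splits are rejected at validation).
* Interaction metrics stop at pairs; higher-order interactions appear only
  through their pairwise projections.
* The direction indicator is this package's rank rule; other conventions
  (e.g. support-mass weighting) would flip no more than the labeling of
  near-symmetric conditions but are not implemented.
* Performance on real data is bounded by the fitted model: the
  interpretation can only surface associations the tree ensemble actually
  uses.
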