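# Methods

This note documents the models, the numerical conventions, and the design
choices behind `qsartrees`, in the spirit of a statistical package's model
documentation. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Problem setting

The package classifies substances as ready biodegradable (RB, the positive
minority class) or not ready biodegradable (NRB) from a fixed table of
molecular descriptors. Descriptors come in three measurement kinds —
continuous indices, ordinal counts, and binary presence flags — and the
class distribution is about 2:1 NRB:RB in both the training split
(284 RB / 553 NRB) and the test split (263 RB / 625 NRB). Both models are
designed around that imbalance rather than around raw accuracy.

## Feature screening

Continuous descriptors are scored by the one-way between/within F statistic
with (J−1, N−J) degrees of freedom; within-class variances use the unbiased
(Nⱼ−1) denominator. Ordinal and flag descriptors are scored by the
likelihood-ratio chi-square G² on the I×J contingency table of distinct
feature values by class, with empty cells contributing zero and
d = (I−1)(J−1) degrees of freedom; ordinal levels are used as-is, not
binned, because the statistic is defined on cell frequencies. Importance is
1 − p clamped to [0, 1]; this saturates at 1.0 for any strongly separating
descriptor, which is how a screening report can show nearly all descriptors
at "100% importance" with a handful below. Degenerate cases are defined, not
errors: a constant feature gets G² = 0 (or F = 0) and p = 1; a continuous
feature with zero pooled within-class variance but separated means gets
p = 0 with a warning. No multiple-testing correction is applied — screening
ranks features, it does not test hypotheses — and it should be run on the
training split only.

## Decision trees

A single weighted binary-tree implementation serves both ensembles.
Candidate splits are thresholds at midpoints between consecutive distinct
sorted values; a 0/1 flag yields its natural partition via the threshold
0.5, and ordinal counts are thresholded like continuous values (they are
ordered counts, so a threshold respects their structure; per-level branching
is deliberately not implemented). Ties between equally scoring splits break
toward the lower feature index, then the lower threshold, making every tree
a deterministic function of (data, weights, parameters, RNG stream).

* **CART regime** (random trees): the split minimizing the weighted-average
  child Gini impurity 1 − Σ p_c²; a split must strictly improve on the
  parent impurity (tolerance 1e−12).
* **C5.0 regime** (boosting): the split maximizing the gain ratio
  IG/SplitInfo with entropies in log base 2 (so two-class entropy lies in
  [0, 1]); candidates need positive information gain and positive split
  information. The gain ratio is implemented in its standard normalized
  form — gain divided by the entropy of the child-size distribution — which
  is the quantity that actually penalizes many-way fragmentation.

Pruning (C5.0 regime only) is bottom-up pessimistic pruning: a subtree
collapses to a leaf when the leaf's error count, inflated to the one-sided
upper binomial confidence bound at CF = 1 − pSeverity/100, does not exceed
the sum of its descendants' inflated errors. The bound is the classic C4.5
convention — the largest rate U with P(≤E errors | N, U) = CF, computed via
the inverse regularized beta function, closed form 1 − CF^(1/N) at E = 0 —
and accepts weighted (non-integer) counts; boosted trees are grown on
weights scaled to count scale (summing to N) so the first trial's pruning
matches the unweighted convention exactly. Branch grafting (promoting the
largest child) is not implemented; only leaf replacement.

Leaf decisions without costs take the heavier class, with exact ties going
to NRB — deterministic and conservative for a minority-positive problem.
With a cost matrix the leaf prediction minimizes expected misclassification
cost: predict RB iff (1−p)·cost(NRB→RB) < p·cost(RB→NRB).

## Balanced random trees

Each of `ntree` (default 200) trees is grown, unpruned and to maximum depth
(child size floor 1), on a balanced bootstrap: m draws with replacement
from the minority class followed by m from the majority class, m being the
minority class size. The in-bag sample therefore has 2m draws with exact
class parity — on 2:1 data this is smaller than the conventional N-draw
bootstrap, and that is the point: the majority class is down-sampled per
tree rather than the minority oversampled globally. At every node a fresh
uniform subset of `nfeature` features is drawn; the default is round(√p),
and the canonical 41-descriptor table is run at nfeature = 7. Prediction is
by unweighted majority vote with ties to NRB; the RB vote fraction, on the
grid {0, 1/ntree, …, 1}, is the ROC score.

OOB machinery: a sample's OOB trees are those whose bootstrap never drew
it. The OOB error is the misclassification rate of per-sample majority
votes over OOB trees only (samples OOB for no tree are excluded with a
warning — possible only for very small ensembles). Permutation importance
permutes one feature's column within a tree's OOB rows, re-measures that
tree's OOB error, and averages the per-tree error increase over trees; no
further normalization is applied, since the measure is meaningful as a
ranking within one fitted ensemble rather than as an absolute quantity. The
permutation RNG stream is derived from (model seed, tree index, feature
index), so importances are reproducible and independent of evaluation
order; a constant feature's importance is exactly zero.

Reproducibility: the fit takes one integer seed; per-tree generators are
spawned from it, and identical (data, params, seed) give identical trees,
votes, OOB error and importances.

## Boosted cost-sensitive C5.0 trees

Boosting runs at most T trials (default 10). Weights start uniform at 1/N —
or, in the cost-sensitive variant, proportional to the misclassification
cost of each sample's true class, normalized to sum 1 (the "data level"
cost injection). Each trial grows a gain-ratio tree on the current
normalized weights (child floor `chsize`, default 2), prunes it at
`pSeverity` (default 75, CF = 0.25), and evaluates its weighted error ε_t
using the same leaf decision rule the committee will use (cost-aware when a
cost matrix is present — the "algorithm level" injection; both injection
points can be switched independently for ablation). Then:

* ε_t = 0: the perfect stage is kept and boosting stops; its β is recorded
  at the floor 1e−10 so the 1/β vote weight is finite and dominant.
* ε_t ≥ 0.5: the stage is discarded and boosting stops (if it is the first
  stage, the model falls back to that single tree with a warning).
* otherwise β_t = ε_t/(1−ε_t) ∈ (0, 1); weights of correctly classified
  samples are multiplied by β_t and all weights renormalized.

The committee votes with weight 1/β_t per stage; the RB share of the
weighted vote total is the ROC score. The weighted error is the plain
misclassification weight sum, not cost-weighted — costs act through the
initial weights and leaf decisions, keeping ε_t interpretable as a
probability. Pruning is applied per trial, so each stage is a finished tree.
The default cost matrix makes misclassifying RB as NRB twice as costly as
the converse, matching the 2:1 class ratio.

## Evaluation

RB is positive everywhere. Seven measures are reported: sensitivity,
specificity, accuracy, precision, F1, FPR = 1 − specificity and
FNR = 1 − sensitivity; the identities hold exactly at full precision, and
report-time rounding is half-up to 2 decimals. A precision with no positive
predictions is reported as 0 with a warning. The ROC curve sweeps
thresholds over descending distinct scores with tied scores grouped into a
single point; the trapezoidal AUROC under that convention equals the
Mann–Whitney pair-concordance statistic with ties counted one half (checked
to 1e−12 against an independent pairwise oracle and scikit-learn).
`accuracy_from_rates` and `f1_from_rates` reconstruct a results table's
accuracy and F1 from its printed sensitivity/specificity/precision and the
test class sizes (263/625); the test suite uses them to verify published
rows for internal consistency and pins down the handful of cells that are
arithmetically inconsistent between tables.

## Synthetic data

The generator is the package's study stand-in, not a molecular simulator.
One scalar effect size maps onto all three kinds: continuous features are
Gaussian with class means separated by effect·SD; ordinal features are
Poisson with class rate ratio exp(effect); flags are Bernoulli with a
class log-odds shift equal to the effect. Noise features are identically
distributed across classes. Each feature has its own RNG stream spawned
from the table seed, so adding or editing one feature leaves the others'
draws unchanged.

The paper-shaped configuration reproduces the study's dimensions: 41
features with the canonical kind mix (17 continuous, 21 ordinal, 3 flag),
train 284 RB / 553 NRB and test 263 RB / 625 NRB drawn from one population.
Ten descriptors are informative with graded effects from 1.6 down to 0.5
(in the single-scalar units above), named after and led decisively by
`SpMax_L` so that the importance machinery has a known ground truth to
recover. Defaults were chosen once to emulate an informative-but-noisy
descriptor table on which a tuned ensemble separates the classes well
without being trivial.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real descriptor data: inter-feature correlation
(real 2D matrix-based descriptors are strongly collinear; permutation
importance is known to split credit among correlated features), the
distribution shift between a study's validation sources (train and test
come from one population here, so synthetic test metrics run optimistic),
heavy tails and mixed discrete-continuous marginals of real descriptors,
and any structure-activity mechanism. Absolute metric values on synthetic
data are properties of the generator; only the pipeline's behavior
(calibration, invariants, directional effects, recovery of planted signal)
transfers.

## Problem sizes and numerical choices

Simulation-backed tests run at deliberately small scale chosen as the
smallest sizes at which the checked effects are stable: feature-recovery
runs use 80-sample tables with 6 features and 25 trees over 50 seeds;
the balanced-vs-plain comparison uses 180-sample 2:1 tables with 40 trees,
paired over 20 seeds; null-calibration uses 2000 independent features of
100 samples. The acceptance script runs the full study-scale configuration
(837/888 rows, 200 trees). Floating-point tolerances: split-score
comparisons and pruning use 1e−12; partition weight checks 1e−9. All
randomness flows from explicit integer seeds through NumPy `SeedSequence`
spawning.

## Known limitations

* Ordinal features are thresholded, not branched per level; high-cardinality
  nominal features are out of scope (none exist in the 41-descriptor
  schema).
* Missing values are rejected rather than imputed or fractionally routed.
* The boosted model's ε_t is not cost-weighted (a defensible variant that
  would couple the two cost injections).
* Permutation importance inherits its usual caveats under correlated
  features; the OOB error of the balanced ensemble estimates error under
  balanced sampling, not under the native class distribution.
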