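# Methods

## The modelling problem

The package predicts intrinsic aqueous solubility, logS = log10 of the
molar solubility of a compound's neutral form, from a numeric table of
molecular descriptors (rows = compounds, columns = descriptors such as a
CDK export). It implements the complete small-data QSPR workflow: curate
the descriptor table, fit several regressors, choose a consensus on an
internal validation set, and score predictions with the metric conventions
standard in solubility benchmarking. Everything downstream assumes one
trustworthy logS value per compound and a training pool cleansed of any
compound that also appears in a test set (id matching is case- and
whitespace-insensitive, by identifier only; no structure matching).

## Descriptor curation

Fixed order: (1) drop any descriptor undefined for any compound; (2) drop
zero-variance descriptors, judged on training rows when a split is
supplied (a feature constant only on test rows survives); (3) optionally
prune correlated pairs; (4) min-max scale. Re-applying the fitted pipeline
to its own output is the identity.

Correlation pruning removes one member of every descriptor pair with
|Pearson r| > 0.8, keeping the member with the larger |r| against logS
over the training rows. The pair-processing order is not forced by the
definition, so we fix it deterministically: pairs are processed greedily
in descending |r| (ties by lexicographic name pair), skipping pairs whose
loser is already gone; a tie on |r with logS| keeps the lexicographically
first name and is flagged in the audit. The result is independent of input
column order.

Scaling maps each descriptor through (VALUE − MIN)/(MAX − MIN) with MIN and
MAX taken from training rows only, so no test information leaks into model
construction; training values land in [0, 1] and test values may fall
outside, deliberately unclipped — the map is affine and clipping would
silently distort distances. A constant training column at scaling time is
an error (it means the zero-variance filter was skipped). Scaling followed
by unscaling recovers inputs to floating-point accuracy.

Tree ensembles receive the unpruned, unscaled table (they are robust to
redundant descriptors); pruning and scaling serve the distance-based
models, where every dimension must contribute comparably.

## Regression trees and ensembles

One CART-style growing routine underlies all three ensembles. The split
criterion is the regression standard: maximise
SSE(parent) − SSE(left) − SSE(right). Exhaustive search places candidate
thresholds at midpoints between adjacent distinct sorted values (invariant
to monotone jitter below data resolution); rows route left iff
value ≤ threshold. Recursion stops when a node cannot produce two children
of at least `min_node_size` rows (default 5, the usual regression default;
configurable), when targets are constant, or when no candidate split has
positive gain; there is no depth limit. Leaves predict the mean target of
their rows, so every prediction is bracketed by the training target range.

The three ensembles are configurations of that core:

| method        | per-tree sample        | features per node | cut-points            | default trees |
|---------------|------------------------|-------------------|-----------------------|---------------|
| Bagging       | bootstrap (N of N with replacement) | all  | exhaustive            | 100           |
| Random Forest | bootstrap              | mtry = ⌊p/3⌋      | exhaustive            | 1000          |
| Extra Trees   | full sample            | mtry = ⌈p/3⌉      | one uniform random per feature | 500 |

The Extra Trees cut-point is drawn uniformly inside (node min, node max) of
each candidate feature, one per feature, and the best of those candidate
partitions is taken. Predictions are the unweighted mean over trees.
Per-tree random streams are spawned from the master seed by tree index
(numpy PCG64 via `SeedSequence(seed, spawn_key=(tree_index,))`), so a
fitted ensemble is bit-reproducible and independent of fitting order; the
RNG algorithm and stream discipline are part of the reproducibility
contract, as is the generator's fixed draw order below.

Out-of-bag RMSE predicts each training row only with trees whose bootstrap
excluded it; rows never out-of-bag are skipped and counted, and an empty
out-of-bag set yields NaN with count 0. Descriptor importance is reported
two ways: permutation (mean increase in per-tree out-of-bag MSE after
permuting the feature among that tree's out-of-bag rows; exactly zero for
features a tree never uses) and node purity (total SSE reduction
attributed to the feature over all nodes).

## k-nearest neighbours

Four variants: Euclidean or Manhattan distance, unweighted or
exponentially weighted. The unweighted prediction is the mean logS of the
k nearest training compounds in the scaled descriptor space; the weighted
variant uses w_j = exp(−d_j/h). The bandwidth h defaults to the mean
distance to the selected neighbours of that query, a scale-free choice;
as h → ∞ the weighted mean converges to the unweighted one (asserted in
tests at h = 1e9). If all selected neighbours coincide with the query
(h = 0) the unweighted mean is used. Ties at the k-th distance include all
tied neighbours and average over the expanded set, which makes predictions
independent of training-row order.

k is chosen by leave-one-out cross-validation over k = 2…8 on the training
set, the held-out compound excluded from its own neighbour list; RMSE ties
go to the smaller k (parsimony). Selected k values are data-dependent
outcomes, not constants of the method.

## Vox Machinarum consensus

The consensus prediction for a compound is the median of an odd number m
of member-model predictions; odd crowds only (even sizes are rejected
rather than averaging a middle pair). Membership and size are chosen on
the internal validation set: models are ranked by individual validation
RMSE (ties by AAE, then name), each candidate size m ∈ {3, 5, 7, 9} is
scored by the validation RMSE of the top-m median, and the smallest RMSE
wins with ties to smaller m. When fewer models are available than the
largest candidate size, infeasible sizes are dropped with a warning. The
median is permutation-invariant, monotone in every member, and bracketed
per compound by the member minimum and maximum; no claim is made that it
beats its best member.

## Evaluation conventions

RMSE and AAE in logS units; R² is the squared Pearson correlation (not the
coefficient of determination), undefined — reported as NaN, never 0 — when
either side is constant; SD of observed values uses denominator N (no
Bessel correction) for consistency with RMSE, so RMSE/SD < 1 means the
model beats predicting the mean. Within-threshold counts at 0.5 and 1.0
logS default to the closed comparator (|err| ≤ t, so an error of exactly
1.0 counts as within 1.0), with a strict mode (<) available and logged;
the four-way figure buckets are half-open as conventionally captioned:
[0, 0.5), [0.5, 1.0), [1.0, 2.0], (2.0, ∞). Percentages round half-up to
integers. Display rounding is 3 decimals; raw values are kept internally.
Comparing two solubility compilations evaluates over the id intersection,
treating one set as predictions and the other as the gold standard, and
additionally counts pairs differing by more than one logS unit.

## Synthetic benchmark

The generator emulates the statistical shape of a druglike descriptor
export: default 150 compounds × 173 numeric features, with planted
all-missing columns, constant columns, and six 4-member correlated blocks
(affine copies of a seed column with jitter proportional to the copy's
spread, keeping |r| near 1 so pruning has known targets). The response is
a fixed, documented nonlinear function of five informative uniform latent
features,

    logS = −6 + 2·f1 − 3·f2 + 2·f3·f4 + 1.5·[f5 > 0.5] + ε,

with ε ~ Normal(0, noise_sd²) and noise presets 0.17 ("tight") and 0.62
("loose") matching the inter-laboratory reproducibility of curated versus
literature-harvested solubility compilations. The signal SD is ≈1.35 logS
units, comparable to real tight-set spreads, so RMSE/SD ratios land in a
realistic range.

What the generator does not emulate: real CDK descriptor marginals
(columns are affinely shifted uniforms), discrete/count descriptors,
heavy-tailed or skewed logS distributions, activity cliffs, and any
structure–property relationship beyond the fixed g. Passing the
parameter-recovery tests therefore shows the pipeline recovers a known
nonlinear signal at realistic noise, not that it attains any particular
accuracy on real compounds.

Tiny worked fixtures carry published per-compound literature logS spreads
(griseofulvin, haloperidol, cisapride, amiodarone, clofazimine,
saquinavir, tamoxifen, bisoprolol) with source labels, used by the range
statistics and the comparison examples.

## Problem sizes and runtime choices

Tests and the acceptance script run the benchmark at its native tabular
scale (n = 150, p = 173) but with 100 trees per ensemble — forests of that
size are within a few percent of the RMSE of the full defaults here, and
keep the whole suite fast. Oracle-equivalence checks run on ≤ 30-row
instances where brute-force enumeration is exact. The end-to-end
acceptance run mirrors the study shape: a 153-compound curated pool split
117/36, a 100-compound tight test set and a 32-compound loose test set.

## Known limitations

- Descriptor computation is out of scope; the package consumes CSV tables.
- No SMILES/structure handling; aromatization consistency between training
  and test descriptors is the caller's responsibility upstream.
- Identifier-based overlap removal cannot catch the same structure listed
  under different names.
- The published benchmark tables for the real challenge sets depend on the
  original training compounds, their CDK descriptors and the challenge
  gold-standard values, none of which ship with the package; the synthetic
  benchmark is a statistical stand-in, not a reproduction of those tables.
- MLP and RVM regressors are not implemented; the consensus machinery
  accepts any external model's predictions through `PredictionPanel`.
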