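# voxsol

Intrinsic aqueous solubility prediction with regression tree ensembles,
k-nearest neighbours and a median-of-models consensus.

Poor aqueous solubility is one of the main reasons drug candidates fail, and
predicting the intrinsic solubility of a druglike compound — logS, the
base-10 logarithm of the molar solubility of its neutral form — from
structure-derived molecular descriptors remains a standard QSPR benchmark
problem. A practical complication is that the experimental data themselves
are noisy: inter-laboratory reproducibility for "tight", carefully curated
compilations is around 0.17 logS units, while looser literature-harvested
values scatter by roughly 0.62 logS units, which bounds how accurate any
model can appear.

`voxsol` is a from-scratch, fully seeded implementation of the modelling
stack commonly applied to this problem:

- **Regression tree ensembles** built on a shared CART core (split criterion:
  maximal SSE reduction; route left iff x ≤ t):
  - *Bagging* — bootstrap resampling, all features at every node, exhaustive
    midpoint cut-points (default 100 trees);
  - *Random Forest* — bootstrap resampling, a random `mtry = ⌊p/3⌋` feature
    subset per node, exhaustive cut-points (default 1000 trees);
  - *Extra Trees* — the full sample, a random `mtry = ⌈p/3⌉` subset per node
    and one uniform random cut-point per candidate feature (default 500
    trees);
  with out-of-bag RMSE and permutation/node-purity descriptor importances.
- **Four kNN variants** (Euclidean/Manhattan × unweighted/exponentially
  weighted, w_j = exp(−d_j/h)), with the neighbour count k selected by
  leave-one-out cross-validation over k = 2…8.
- **Vox Machinarum** — a wisdom-of-crowds consensus: the per-compound median
  of an odd number m of model predictions, with the crowd membership
  (top-m models by validation RMSE) and size m ∈ {3, 5, 7, 9} chosen on an
  internal validation set.
- **Leakage-safe descriptor curation** for the distance-based models: drop
  descriptors undefined for any compound, drop zero-variance descriptors,
  prune one of any pair with |Pearson r| > 0.8 (keeping the member better
  correlated with logS over the training set), then min-max scale each
  descriptor with training-set bounds,
  `scaled = (VALUE − MIN) / (MAX − MIN)`. Tree ensembles deliberately
  consume the unpruned, unscaled table.
- **The evaluation suite** used in solubility benchmarking: RMSE, AAE,
  R² (squared Pearson correlation), denominator-N SD of the observed
  values, RMSE/SD, within-0.5/1.0 logS counts, and the four-way error
  buckets used to colour prediction scatter plots, plus statistics for
  comparing two solubility compilations.
- **A synthetic benchmark generator** producing druglike-scale descriptor
  tables (default 150 × 173) with planted correlated blocks, all-missing
  and constant columns, and a nonlinear logS response at the tight (0.17)
  or loose (0.62) noise presets.

It consumes descriptor tables as CSV (e.g. CDK descriptor exports); it does
not compute descriptors itself.

## Worked example

Train the three tree ensembles on a synthetic 117-compound training set,
choose the consensus on the 36-compound validation set, and tabulate:

```python
import pandas as pd
from voxsol import *

data = generate(GeneratorSpec(n_compounds=153, noise_sd=NOISE_TIGHT, seed=11))
table, _ = drop_incomplete_features(data.table)
table, _ = drop_zero_variance(table)
split = split_train_validation(data.solubility, n_validation=36, seed=11)

train, val = table.select_rows(split.train_ids), table.select_rows(split.validation_ids)
y_train, y_val = data.solubility.align_with(train), data.solubility.align_with(val)

results = {
    name: TreeEnsemble(train, y_train, EnsembleConfig(m, n_trees=100, seed=11)).fit()
    for name, m in [("Extra Trees", EnsembleMethod.EXTRA_TREES),
                    ("Random Forest", EnsembleMethod.RANDOM_FOREST),
                    ("Bagging", EnsembleMethod.BAGGING)]
}
panel = PredictionPanel(pd.DataFrame(
    {name: r.predict(val) for name, r in results.items()}, index=val.compound_ids))
truth = pd.Series(y_val, index=val.compound_ids)
vm = VoxMachinarum(panel, truth, sizes=(3,)).fit()

reports = {name: evaluate(panel.frame[name], truth) for name in panel.model_names}
reports["Vox Machinarum (3)"] = evaluate(vm.predict(panel), truth)
print(report_table(reports).to_string())
```

prints

```
                     RMSE  RMSE/SD    AAE     R2   Err<0.5   Err<1.0
Method
Extra Trees         0.852    0.733  0.656  0.721  16 (44%)  26 (72%)
Random Forest       0.831    0.715  0.633  0.667  18 (50%)  28 (78%)
Bagging             0.762    0.655  0.618  0.573  17 (47%)  30 (83%)
Vox Machinarum (3)  0.813    0.699  0.626  0.677  18 (50%)  28 (78%)
```

Each row is one predictor on the 36 held-out compounds: RMSE and AAE in
logS units; RMSE/SD < 1 means the model beats predicting the mean; R² is
the squared Pearson correlation; the last two columns count compounds
predicted within 0.5 and 1.0 logS units. The consensus prediction for each
compound is the median of the three ensembles, so its errors track the
middle of the crowd.

The same workflow is available from a shell via the `voxsol` command
(`simulate`, `train`, `select`, `predict`, `evaluate`, `compare`,
`fixtures`), with every run reproducible from its `--seed`.

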